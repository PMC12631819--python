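"""Model interpretation: permutation importance, top-N clustering ARS, and
pairwise mutation analysis.

Permutation importance works at the granularity of one image cell per
feature: the optimised cross-entropy loss (OCEL) of the trained model is
compared with the loss after shuffling a feature's cell intensities across
samples (PCEL, averaged over repeats); the importance score is
IS = PCEL - OCEL.

Pairwise mutation analysis scores a nucleotide pair (i, j) by mutating both
positions to every alternative base (3 x 3 = 9 double mutants), averaging
the model's coding-potential scores over the nine mutants, and reporting the
contribution C = P_original - P_mutated.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import AgglomerativeClustering
from sklearn.metrics import adjusted_rand_score

from .gfeatures import GapFeatureSpec
from .imaging import FeatureTemplate
from .model import DualPathModel, cross_entropy
from .sequences import RNA_ALPHABET, RnaSequence


@dataclasses.dataclass
class ImportanceReport:
    """Per-feature permutation importance (IS = PCEL - OCEL)."""

    ocel: float
    table: pd.DataFrame            # columns: name, feature_set, subgroup, pcel, is
    n_permutations: int
    seed: int

    @property
    def ranking(self) -> list[str]:
        """Feature names sorted by importance score, descending."""
        return list(self.table.sort_values("is", ascending=False,
                                           kind="stable")["name"])


@dataclasses.dataclass
class MutationScanResult:
    """Eq.-style contribution of one nucleotide pair."""

    i: int                         # 1-based positions
    j: int
    p_original: float
    mutant_scores: np.ndarray      # the 9 double-mutant scores
    p_mutated: float               # their mean
    c_pair: float                  # p_original - p_mutated

    def __post_init__(self) -> None:
        if len(self.mutant_scores) != 9:
            raise ValueError("a pair scan must have exactly 9 mutants")


def _cell_channel(template: FeatureTemplate, name: str) -> tuple[int, int, int]:
    r, c = template.placement[name]
    ch = template.subgroups.index(template.subgroup_of[name])
    return r, c, ch


def permutation_importance(
    model: DualPathModel,
    xd: np.ndarray, xg: np.ndarray, y: np.ndarray,
    template_d: FeatureTemplate, template_g: FeatureTemplate,
    n_permutations: int = 5, seed: int = 0,
    features: Sequence[str] | None = None,
) -> ImportanceReport:
    """Permutation importance of every feature cell.

    For each feature, the intensities of its assigned cell (in its subgroup
    channel) are shuffled across samples ``n_permutations`` times; PCEL is
    the mean permuted loss.  Cells whose intensities are identical across
    samples give IS = 0 exactly (the permutation is a no-op).  The D-path
    embedding is cached while G-features are permuted and vice versa, which
    gives identical results to a full forward pass at half the cost.

    ``features`` restricts the scan (default: all features of both sets).
    """
    if len(y) < 20:
        raise ValueError("permutation importance needs at least 20 samples")
    rng = np.random.default_rng(seed)
    ed, eg = model.path_embeddings(xd, xg)
    ocel = cross_entropy(model.proba_from_embeddings(ed, eg), y)

    all_feats = ([(n, "D") for n in template_d.placement]
                 + [(n, "G") for n in template_g.placement])
    if features is not None:
        wanted = set(features)
        all_feats = [(n, s) for n, s in all_feats if n in wanted]
        missing = wanted - {n for n, _ in all_feats}
        if missing:
            raise KeyError(f"features not in any template: {sorted(missing)[:5]}")

    n = len(y)
    rows = []
    for name, fset in all_feats:
        template = template_d if fset == "D" else template_g
        x = xd if fset == "D" else xg
        r, c, ch = _cell_channel(template, name)
        col = x[:, r, c, ch]
        if np.all(col == col[0]):
            pcel = ocel     # constant cell: shuffling changes nothing
        else:
            # all repeats in one stacked forward pass through the one path
            # the feature lives in; the other path's embedding is reused
            stack = np.tile(x, (n_permutations, 1, 1, 1))
            for p in range(n_permutations):
                perm = rng.permutation(n)
                stack[p * n:(p + 1) * n, r, c, ch] = col[perm]
            ep = model.path_embedding(stack, "d" if fset == "D" else "g")
            losses = []
            for p in range(n_permutations):
                sl = slice(p * n, (p + 1) * n)
                if fset == "D":
                    proba = model.proba_from_embeddings(ep[sl], eg)
                else:
                    proba = model.proba_from_embeddings(ed, ep[sl])
                losses.append(cross_entropy(proba, y))
            pcel = float(np.mean(losses))
        rows.append({"name": name, "feature_set": fset,
                     "subgroup": template.subgroup_of[name],
                     "pcel": pcel, "is": pcel - ocel})
    table = pd.DataFrame(rows)
    return ImportanceReport(ocel=ocel, table=table,
                            n_permutations=n_permutations, seed=seed)


def top_n_ars(feature_matrix: np.ndarray, labels: np.ndarray,
              ranking: Sequence[str], feature_names: Sequence[str],
              n_top: int, linkage: str = "ward") -> float:
    """Adjusted Rand score of hierarchical clustering on the top-N features.

    Ward-linkage (Euclidean) agglomerative clustering of the samples on the
    top-N ranked feature columns, cut at the number of true classes, compared
    with the true labels by the adjusted Rand index.
    """
    if not 1 <= n_top <= len(ranking):
        raise ValueError(f"N must be in [1, {len(ranking)}]")
    labels = np.asarray(labels)
    index = {name: i for i, name in enumerate(feature_names)}
    cols = [index[name] for name in ranking[:n_top]]
    sub = np.asarray(feature_matrix, dtype=float)[:, cols]
    k = len(np.unique(labels))
    pred = AgglomerativeClustering(n_clusters=k, linkage=linkage).fit_predict(sub)
    return float(adjusted_rand_score(labels, pred))


# ---------------------------------------------------------------------------
# pairwise mutation analysis
# ---------------------------------------------------------------------------

ScoreFn = Callable[[list[RnaSequence]], np.ndarray]


class SequenceScorer:
    """End-to-end scorer: sequences -> rendered images -> class probability.

    For binary coding tasks the returned score is the Coding Potential Score
    (CPS): the softmax probability of the positive (coding) class.
    """

    def __init__(self, model: DualPathModel, template_d: FeatureTemplate,
                 template_g: FeatureTemplate, positive_class: int = 1):
        self.model = model
        self.template_d = template_d
        self.template_g = template_g
        self.positive_class = positive_class

    def predict_proba(self, seqs: list[RnaSequence]) -> np.ndarray:
        from .imaging import render_corpus_channels
        xd, xg = render_corpus_channels(seqs, self.template_d, self.template_g)
        return self.model.predict_proba(xd, xg)

    def __call__(self, seqs: list[RnaSequence]) -> np.ndarray:
        return self.predict_proba(seqs)[:, self.positive_class]


def _mutants(seq: RnaSequence, i: int, j: int) -> list[RnaSequence]:
    """All 9 double mutants at 1-based positions i and j."""
    L = seq.length
    if not (1 <= i <= L and 1 <= j <= L):
        raise ValueError(f"positions ({i}, {j}) out of range for length {L}")
    if i == j:
        raise ValueError("pair positions must be distinct")
    s = seq.residues
    alts_i = [b for b in RNA_ALPHABET if b != s[i - 1]]
    alts_j = [b for b in RNA_ALPHABET if b != s[j - 1]]
    out = []
    for a in alts_i:
        for b in alts_j:
            mut = list(s)
            mut[i - 1] = a
            mut[j - 1] = b
            out.append(RnaSequence(id=f"{seq.id}|m{i}{a}_{j}{b}",
                                   residues="".join(mut)))
    return out


def scan_pair(seq: RnaSequence, score_fn: ScoreFn, i: int, j: int,
              p_original: float | None = None) -> MutationScanResult:
    """Score one nucleotide pair: 9 double mutants, mean, and contribution."""
    if p_original is None:
        p_original = float(score_fn([seq])[0])
    scores = np.asarray(score_fn(_mutants(seq, i, j)), dtype=float)
    p_mut = float(scores.mean())
    return MutationScanResult(i=i, j=j, p_original=p_original,
                              mutant_scores=scores, p_mutated=p_mut,
                              c_pair=p_original - p_mut)


def enumerate_window_pairs(length: int, start: int = 1,
                           end: int | None = None) -> list[tuple[int, int]]:
    """All position pairs (i < j), 1-based, within [start, end]."""
    end = length if end is None else end
    if end - start + 1 < 2:
        raise ValueError("window length must be >= 2")
    if start < 1 or end > length:
        raise ValueError("window out of range")
    return [(i, j) for i in range(start, end + 1)
            for j in range(i + 1, end + 1)]


def enumerate_gfeature_pairs(seq: RnaSequence, feature_name: str
                             ) -> list[tuple[int, int]]:
    """Pairs (i, j), 1-based, matching a named gap feature.

    For ``k-XY`` these are positions with residue(i) == X,
    residue(j) == Y and j - i - 1 == k (e.g. 37-GC matches (2, 40)).
    """
    spec = GapFeatureSpec.from_name(feature_name)
    s = seq.residues
    k = spec.gap
    return [(i + 1, i + k + 2)
            for i in range(seq.length - k - 1)
            if s[i] == spec.first and s[i + k + 1] == spec.second]


def pairwise_mutation_scan(seq: RnaSequence, score_fn: ScoreFn,
                           pairs: Sequence[tuple[int, int]]
                           ) -> list[MutationScanResult]:
    """Mutation-scan a list of position pairs with a shared original score."""
    p_orig = float(score_fn([seq])[0])
    return [scan_pair(seq, score_fn, i, j, p_original=p_orig)
            for i, j in pairs]


def contribution_matrix(results: Sequence[MutationScanResult],
                        length: int) -> np.ndarray:
    """Symmetric (length x length) matrix of C_pair values (NaN where unscanned)."""
    mat = np.full((length, length), np.nan)
    for r in results:
        mat[r.i - 1, r.j - 1] = mat[r.j - 1, r.i - 1] = r.c_pair
    return mat
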