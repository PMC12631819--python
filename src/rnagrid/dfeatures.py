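"""Descriptor D-features: sequence-intrinsic, structure-based and
physicochemical CTD descriptors.

The default registry emits 753 features in 14 subgroups: 314 classical
descriptors (ORF, codon/k-mer composition, entropy, autocorrelation, global
composition, secondary structure, EIIP power spectrum, structure-graph
topology) and 439 Composition-Transition-Distribution (CTD) descriptors
derived from 20 per-nucleotide physicochemical properties in 6 subgroups.
Each subgroup belongs to one of three classes: sequence-intrinsic,
structure-based, or physicochemical-ctd.

Secondary-structure and graph features are computed on a centred window of at
most ``SS_WINDOW`` nucleotides: the Nussinov recursion is cubic in the window
length, and local structure statistics saturate well below transcript scale.
"""

from __future__ import annotations

import dataclasses
import functools
import shutil
import subprocess
from importlib import resources

import numpy as np
from numba import njit
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .gfeatures import FeatureVector, encode
from .sequences import RNA_ALPHABET, RnaSequence

#: Standard electron-ion interaction potential values for RNA bases.
EIIP = {"A": 0.1260, "C": 0.1340, "G": 0.0806, "U": 0.0289}

SS_WINDOW = 200
_N_EIIP_BINS = 32
_AUTOCORR_LAGS = 12

#: subgroup -> feature class; order here fixes the output order of subgroups.
SUBGROUP_CLASS = {
    "orf": "sequence-intrinsic",
    "kmer_codon": "sequence-intrinsic",
    "entropy": "sequence-intrinsic",
    "autocorrelation": "sequence-intrinsic",
    "composition": "sequence-intrinsic",
    "secondary_structure": "structure-based",
    "eiip_spectrum": "structure-based",
    "structure_graph": "structure-based",
    "ctd_hbond": "physicochemical-ctd",
    "ctd_basicity": "physicochemical-ctd",
    "ctd_tpsa": "physicochemical-ctd",
    "ctd_logp": "physicochemical-ctd",
    "ctd_solubility": "physicochemical-ctd",
    "ctd_pathlen": "physicochemical-ctd",
}

_STOPS = ("UAA", "UAG", "UGA")
_TRIPLETS = tuple(a + b + c for a in RNA_ALPHABET for b in RNA_ALPHABET
                  for c in RNA_ALPHABET)


@dataclasses.dataclass(frozen=True)
class PropertyTable:
    """One physicochemical property: per-nucleotide value and class partition.

    Class ids are contiguous from 1; the partition orders nucleotides from
    low to high property value.
    """

    name: str
    values: dict[str, float]
    classes: dict[str, int]
    subgroup: str = ""

    def __post_init__(self) -> None:
        if set(self.values) != set(RNA_ALPHABET) or set(self.classes) != set(RNA_ALPHABET):
            raise ValueError(f"property {self.name}: need all four nucleotides")
        ids = sorted(set(self.classes.values()))
        if ids != list(range(1, len(ids) + 1)):
            raise ValueError(f"property {self.name}: class ids must be 1..g")

    @property
    def n_classes(self) -> int:
        return max(self.classes.values())


@functools.lru_cache(maxsize=1)
def load_property_registry() -> tuple[PropertyTable, ...]:
    """The 20 CTD properties shipped with the package, in registry order."""
    text = (resources.files("rnagrid") / "data" / "ctd_properties.tsv").read_text()
    props = []
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        props.append(PropertyTable(
            name=f[0], subgroup=f[1],
            values=dict(zip("ACGU", map(float, f[2:6]))),
            classes=dict(zip("ACGU", map(int, f[6:10]))),
        ))
    return tuple(props)


# ---------------------------------------------------------------------------
# ORF / k-mer / entropy / autocorrelation / composition
# ---------------------------------------------------------------------------

def _longest_orf_in_frame(s: str, frame: int) -> tuple[int, int, int]:
    """(length_nt, start_index, has_stop) for the longest ORF in one frame.

    An ORF runs from an AUG to the first in-frame stop (stop included); if no
    stop follows, it runs to the end of the frame, truncated to a codon
    multiple (has_stop 0).
    """
    best = (0, -1, 0)
    codons = [s[i:i + 3] for i in range(frame, len(s) - 2, 3)]
    i = 0
    while i < len(codons):
        if codons[i] == "AUG":
            j = i
            while j < len(codons) and codons[j] not in _STOPS:
                j += 1
            if j < len(codons):
                length, stop = 3 * (j - i + 1), 1
            else:
                length, stop = 3 * (j - i), 0
            if length > best[0]:
                best = (length, frame + 3 * i, stop)
            i = j + 1
        else:
            i += 1
    return best


def orf_features(seq: RnaSequence) -> dict[str, float]:
    """Longest-ORF statistics over the three forward frames.

    Returns the longest ORF length (nt, divisible by 3), its coverage of the
    sequence, integrity (1 if it has both an AUG start and an in-frame stop),
    log10(length + 1), and per-frame lengths and coverages.
    """
    s, L = seq.residues, seq.length
    per_frame = [_longest_orf_in_frame(s, f) for f in range(3)]
    lengths = [p[0] for p in per_frame]
    best = max(range(3), key=lambda f: lengths[f])
    out = {
        "orf_length": float(lengths[best]),
        "orf_coverage": lengths[best] / L,
        "orf_integrity": float(per_frame[best][2] if lengths[best] else 0),
        "orf_log_length": float(np.log10(lengths[best] + 1)),
    }
    for f in range(3):
        out[f"orf_length_frame{f + 1}"] = float(lengths[f])
        out[f"orf_coverage_frame{f + 1}"] = lengths[f] / L
    return out


def _kmer_codon_features(seq: RnaSequence) -> dict[str, float]:
    """Global trinucleotide fractions + codon usage inside the longest ORF."""
    s = encode(seq)
    out: dict[str, float] = {}
    if len(s) >= 3:
        tri = np.bincount(s[:-2] * 16 + s[1:-1] * 4 + s[2:], minlength=64)
        tri = tri / tri.sum()
    else:
        tri = np.zeros(64)
    for t, v in zip(_TRIPLETS, tri):
        out[f"kmer_tri_{t}"] = float(v)
    # codon usage restricted to the longest ORF (zeros when there is none)
    orf = max((_longest_orf_in_frame(seq.residues, f) for f in range(3)),
              key=lambda p: p[0])
    codon = np.zeros(64)
    if orf[0] >= 3:
        region = s[orf[1]: orf[1] + orf[0]]
        codes = region[0::3] * 16 + region[1::3] * 4 + region[2::3]
        codon = np.bincount(codes, minlength=64).astype(float)
        codon /= codon.sum()
    for t, v in zip(_TRIPLETS, codon):
        out[f"codon_{t}"] = float(v)
    return out


def _entropy_features(seq: RnaSequence) -> dict[str, float]:
    """Shannon entropy of the k-mer distribution, k = 1..4, raw and normalised."""
    s = encode(seq)
    out: dict[str, float] = {}
    for k in range(1, 5):
        if len(s) >= k:
            codes = np.zeros(len(s) - k + 1, dtype=np.int64)
            for j in range(k):
                codes = codes * 4 + s[j: len(s) - k + 1 + j]
            p = np.bincount(codes, minlength=4 ** k).astype(float)
            p = p[p > 0] / p.sum()
            h = float(-(p * np.log2(p)).sum())
        else:
            h = 0.0
        out[f"entropy_k{k}"] = h
        out[f"entropy_norm_k{k}"] = h / (2 * k)
    return out


def _autocorr_features(seq: RnaSequence) -> dict[str, float]:
    """P(base at t and t+lag are both b), per base, lags 1..12."""
    s = encode(seq)
    out: dict[str, float] = {}
    for bi, b in enumerate(RNA_ALPHABET):
        track = (s == bi).astype(float)
        for lag in range(1, _AUTOCORR_LAGS + 1):
            if len(track) > lag:
                v = float(np.mean(track[:-lag] * track[lag:]))
            else:
                v = 0.0
            out[f"autocorr_{b}_lag{lag}"] = v
    return out


def _composition_features(seq: RnaSequence) -> dict[str, float]:
    s = encode(seq)
    out: dict[str, float] = {}
    mono = np.bincount(s, minlength=4) / len(s)
    for b, v in zip(RNA_ALPHABET, mono):
        out[f"comp_{b}"] = float(v)
    if len(s) >= 2:
        di = np.bincount(s[:-1] * 4 + s[1:], minlength=16) / (len(s) - 1)
    else:
        di = np.zeros(16)
    for i, x in enumerate(RNA_ALPHABET):
        for j, y in enumerate(RNA_ALPHABET):
            out[f"comp_di_{x}{y}"] = float(di[i * 4 + j])
    return out


# ---------------------------------------------------------------------------
# Secondary structure (Nussinov maximum base pairing)
# ---------------------------------------------------------------------------

# complementarity (AU, GC, GU wobble), indexed A=0 C=1 G=2 U=3
_CAN_PAIR = np.zeros((4, 4), dtype=np.int8)
for _x, _y in ("AU", "UA", "GC", "CG", "GU", "UG"):
    _CAN_PAIR["ACGU".index(_x), "ACGU".index(_y)] = 1

_MIN_LOOP = 3


@njit(cache=False)
def _nussinov_fill(s, can_pair, min_loop):  # pragma: no cover - numba kernel
    L = s.shape[0]
    N = np.zeros((L, L), dtype=np.int32)
    for d in range(min_loop + 1, L):
        for i in range(L - d):
            j = i + d
            best = N[i + 1, j] if i + 1 <= j else 0
            if N[i, j - 1] > best:
                best = N[i, j - 1]
            if can_pair[s[i], s[j]] and j - i - 1 >= min_loop:
                v = 1 + (N[i + 1, j - 1] if i + 1 <= j - 1 else 0)
                if v > best:
                    best = v
            for k in range(i + 1, j):
                v = N[i, k] + N[k + 1, j]
                if v > best:
                    best = v
            N[i, j] = best
    return N


def nussinov_pairs(s: np.ndarray) -> list[tuple[int, int]]:
    """Base pairs (0-based index tuples) of a maximum-pairing Nussinov fold."""
    L = len(s)
    if L < _MIN_LOOP + 2:
        return []
    N = _nussinov_fill(s, _CAN_PAIR, _MIN_LOOP)
    pairs: list[tuple[int, int]] = []
    stack = [(0, L - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or N[i, j] == 0:
            continue
        if N[i + 1, j] == N[i, j]:
            stack.append((i + 1, j))
        elif N[i, j - 1] == N[i, j]:
            stack.append((i, j - 1))
        elif (_CAN_PAIR[s[i], s[j]] and j - i - 1 >= _MIN_LOOP
              and N[i, j] == 1 + (N[i + 1, j - 1] if i + 1 <= j - 1 else 0)):
            pairs.append((i, j))
            stack.append((i + 1, j - 1))
        else:
            for k in range(i + 1, j):
                if N[i, k] + N[k + 1, j] == N[i, j]:
                    stack.append((i, k))
                    stack.append((k + 1, j))
                    break
    return sorted(pairs)


def _window(s: np.ndarray, width: int = SS_WINDOW) -> np.ndarray:
    if len(s) <= width:
        return s
    off = (len(s) - width) // 2
    return s[off: off + width]


def _stems(pairs: list[tuple[int, int]]) -> list[int]:
    """Lengths of maximal runs of stacked pairs ((i,j),(i+1,j-1),...)."""
    pairset = set(pairs)
    lengths = []
    for (i, j) in pairs:
        if (i - 1, j + 1) in pairset:
            continue  # not the outermost pair of its stem
        n = 1
        while (i + n, j - n) in pairset:
            n += 1
        lengths.append(n)
    return lengths


_PAIR_WEIGHT = {"GC": 3.0, "CG": 3.0, "AU": 2.0, "UA": 2.0, "GU": 1.0, "UG": 1.0}


def structure_features(seq: RnaSequence, engine: str = "builtin",
                       _pairs: list[tuple[int, int]] | None = None) -> dict[str, float]:
    """Secondary-structure statistics from a maximum base-pairing fold.

    The builtin engine is a deterministic Nussinov dynamic program (minimum
    hairpin loop 3, AU/GC/GU pairs).  ``engine='external'`` substitutes
    thermodynamic folding via the RNAfold command-line tool and adds the
    minimum free energy per nucleotide; if RNAfold is not on PATH an explicit
    error instructs falling back to the builtin engine.
    """
    s_full = encode(seq)
    s = _window(s_full)
    L = len(s)
    if engine == "builtin":
        pairs = nussinov_pairs(s) if _pairs is None else _pairs
        extra: dict[str, float] = {}
    elif engine == "external":
        pairs, mfe = _rnafold_pairs(seq, s)
        extra = {"ss_mfe_per_nt": mfe / L}
    else:
        raise ValueError(f"unknown structure engine {engine!r}")

    paired = np.zeros(L, dtype=bool)
    for i, j in pairs:
        paired[i] = paired[j] = True
    stems = _stems(pairs)
    pairset = set(pairs)
    hairpins = [(i, j) for i, j in pairs
                if not any(i < a and b < j for a, b in pairset if (a, b) != (i, j))]
    loop_sizes = [j - i - 1 for i, j in hairpins]
    out = {
        "ss_paired_fraction": float(paired.mean()) if L else 0.0,
        "ss_n_stems": float(len(stems)),
        "ss_n_hairpins": float(len(hairpins)),
        "ss_pairs_per_nt": len(pairs) / L if L else 0.0,
    }
    base_counts = np.bincount(s, minlength=4)
    for bi, b in enumerate(RNA_ALPHABET):
        n_b = base_counts[bi]
        out[f"ss_paired_frac_{b}"] = float(paired[s == bi].sum() / n_b) if n_b else 0.0
    kinds = {"GC": 0, "AU": 0, "GU": 0}
    for i, j in pairs:
        pr = RNA_ALPHABET[s[i]] + RNA_ALPHABET[s[j]]
        kinds[pr if pr in kinds else pr[::-1]] += 1
    n_pairs = max(len(pairs), 1)
    for kind in ("GC", "AU", "GU"):
        out[f"ss_pair_frac_{kind}"] = kinds[kind] / n_pairs if pairs else 0.0
    out["ss_mean_stem_len"] = float(np.mean(stems)) if stems else 0.0
    out["ss_max_stem_len"] = float(max(stems)) if stems else 0.0
    out["ss_mean_loop_len"] = float(np.mean(loop_sizes)) if loop_sizes else 0.0
    out["ss_max_loop_len"] = float(max(loop_sizes)) if loop_sizes else 0.0

    def _max_run(mask: np.ndarray) -> float:
        best = cur = 0
        for v in mask:
            cur = cur + 1 if v else 0
            best = max(best, cur)
        return float(best)

    out["ss_max_paired_run"] = _max_run(paired)
    out["ss_max_unpaired_run"] = _max_run(~paired)
    bins = np.array_split(paired, 10)
    for i, b in enumerate(bins, 1):
        out[f"ss_paired_profile_bin{i}"] = float(b.mean()) if len(b) else 0.0
    hist = np.zeros(8)
    for n in stems:
        hist[min(n, 8) - 1] += 1
    for i, v in enumerate(hist, 1):
        out[f"ss_stem_len_hist{i}"] = float(v)
    lhist = np.zeros(5)
    for n in loop_sizes:
        lhist[min(max(n - 3, 0), 4)] += 1
    for i, v in enumerate(lhist, 1):
        out[f"ss_loop_len_hist{i}"] = float(v)
    out.update(extra)
    return out


def _rnafold_pairs(seq: RnaSequence, s: np.ndarray) -> tuple[list[tuple[int, int]], float]:
    """Thermodynamic fold of the windowed sequence via the RNAfold CLI."""
    if shutil.which("RNAfold") is None:
        raise RuntimeError(
            "external structure engine requires the RNAfold executable on "
            "PATH; it was not found — fall back to engine='builtin'"
        )
    residues = "".join(RNA_ALPHABET[i] for i in s)
    proc = subprocess.run(
        ["RNAfold", "--noPS"], input=f">{seq.id}\n{residues}\n",
        capture_output=True, text=True, check=True)
    lines = proc.stdout.strip().splitlines()
    struct_line = lines[-1]
    db = struct_line.split()[0]
    mfe = float(struct_line[struct_line.rfind("(") + 1: struct_line.rfind(")")])
    stack, pairs = [], []
    for i, ch in enumerate(db):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            pairs.append((stack.pop(), i))
    return sorted(pairs), mfe


# ---------------------------------------------------------------------------
# EIIP power spectrum
# ---------------------------------------------------------------------------

def eiip_spectrum_features(seq: RnaSequence) -> dict[str, float]:
    """Fourier power spectrum of the EIIP-mapped sequence.

    The period-3 peak (power at the frequency bin nearest L/3) relative to
    the mean power is the classic coding-region signal.  Also returns the
    spectral entropy and a 32-bin normalised power profile.
    """
    L = seq.length
    if L < 3:
        raise ValueError("EIIP spectrum needs at least 3 residues")
    x = np.array([EIIP[b] for b in seq.residues])
    power = np.abs(np.fft.fft(x)) ** 2
    nz = power[1:]  # exclude the DC component
    p3 = float(power[round(L / 3)])
    mean_p = float(nz.mean())
    total = float(nz.sum())
    out = {
        "eiip_period3_power": p3,
        "eiip_mean_power": mean_p,
        "eiip_snr": p3 / mean_p if mean_p > 0 else 0.0,
    }
    if total > 0:
        q = nz / total
        q = q[q > 0]
        out["eiip_spectral_entropy"] = float(-(q * np.log2(q)).sum())
    else:
        out["eiip_spectral_entropy"] = 0.0
    half = power[1: L // 2 + 1]
    chunks = np.array_split(half, _N_EIIP_BINS)
    for i, c in enumerate(chunks, 1):
        out[f"eiip_power_bin{i}"] = float(c.sum() / total) if total > 0 and len(c) else 0.0
    return out


# ---------------------------------------------------------------------------
# Structure-graph topology
# ---------------------------------------------------------------------------

def _graph_topology_features(seq: RnaSequence,
                             pairs: list[tuple[int, int]] | None = None) -> dict[str, float]:
    """Topological indices of the backbone + base-pair contact graph."""
    s = _window(encode(seq))
    L = len(s)
    if pairs is None:
        pairs = nussinov_pairs(s)
    edges = [(i, i + 1) for i in range(L - 1)] + list(pairs)
    adj = np.zeros((L, L))
    for i, j in edges:
        adj[i, j] = adj[j, i] = 1.0
    deg = adj.sum(axis=1)
    n_edges = len(edges)
    paired = np.zeros(L, dtype=bool)
    for i, j in pairs:
        paired[i] = paired[j] = True
    out = {
        "gt_mean_degree": float(deg.mean()),
        "gt_var_degree": float(deg.var()),
        "gt_max_degree": float(deg.max()),
        "gt_frac_deg1": float((deg == 1).mean()),
        "gt_frac_deg2": float((deg == 2).mean()),
        "gt_frac_deg3": float((deg >= 3).mean()),
        "gt_edges_per_nt": n_edges / L,
        "gt_density": 2 * n_edges / (L * (L - 1)) if L > 1 else 0.0,
        "gt_frac_paired": float(paired.mean()),
    }
    for bi, b in enumerate(RNA_ALPHABET):
        m = s == bi
        out[f"gt_mean_degree_{b}"] = float(deg[m].mean()) if m.any() else 0.0
    p = deg / deg.sum()
    p = p[p > 0]
    out["gt_deg_entropy"] = float(-(p * np.log2(p)).sum())
    ev = np.sort(np.linalg.eigvalsh(adj))[::-1]
    out["gt_adj_lam1"] = float(ev[0])
    out["gt_adj_lam2"] = float(ev[1]) if L > 1 else 0.0
    out["gt_adj_lam3"] = float(ev[2]) if L > 2 else 0.0
    out["gt_adj_energy_per_nt"] = float(np.abs(ev).sum() / L)
    lap = np.diag(deg) - adj
    lev = np.sort(np.linalg.eigvalsh(lap))
    out["gt_lap_lam2"] = float(lev[1]) if L > 1 else 0.0
    out["gt_lap_lammax"] = float(lev[-1])
    dist = shortest_path(csr_matrix(adj), method="D", unweighted=True)
    finite = dist[np.isfinite(dist)]
    out["gt_mean_sp"] = float(finite[finite > 0].mean()) if (finite > 0).any() else 0.0
    ecc = dist.max(axis=1)
    out["gt_diameter"] = float(ecc.max())
    out["gt_mean_ecc"] = float(ecc.mean())
    out["gt_wiener_per_pair"] = float(finite.sum() / (L * (L - 1))) if L > 1 else 0.0
    return out


# ---------------------------------------------------------------------------
# CTD encoding
# ---------------------------------------------------------------------------

def ctd_features(seq: RnaSequence, table: PropertyTable) -> dict[str, float]:
    """Composition-Transition-Distribution encoding for one property.

    With g classes this yields g composition fractions, g(g-1)/2 transition
    rates (adjacent positions whose classes differ as that unordered pair,
    over L-1), and 5g positional quantiles (first, 25/50/75th nearest-rank
    percentile and last occurrence of each class, 1-based, divided by L;
    zeros for an absent class).
    """
    L = seq.length
    if L < 2:
        raise ValueError("CTD needs at least 2 residues")
    g = table.n_classes
    cls = np.array([table.classes[b] for b in seq.residues])
    name = table.name
    out: dict[str, float] = {}
    counts = np.bincount(cls, minlength=g + 1)[1:]
    for c in range(1, g + 1):
        out[f"ctd_{name}_comp_c{c}"] = counts[c - 1] / L
    a, b = cls[:-1], cls[1:]
    lo, hi = np.minimum(a, b), np.maximum(a, b)
    for i in range(1, g + 1):
        for j in range(i + 1, g + 1):
            n_ij = int(np.count_nonzero((lo == i) & (hi == j)))
            out[f"ctd_{name}_tran_c{i}c{j}"] = n_ij / (L - 1)
    qlabels = ("first", "p25", "p50", "p75", "last")
    for c in range(1, g + 1):
        pos = np.flatnonzero(cls == c) + 1  # 1-based
        m = len(pos)
        if m == 0:
            pts = [0.0] * 5
        else:
            ranks = [1, max(int(np.ceil(0.25 * m)), 1),
                     max(int(np.ceil(0.50 * m)), 1),
                     max(int(np.ceil(0.75 * m)), 1), m]
            pts = [pos[r - 1] / L for r in ranks]
        for lab, v in zip(qlabels, pts):
            out[f"ctd_{name}_dist_c{c}_{lab}"] = float(v)
    return out


# ---------------------------------------------------------------------------
# Full extraction
# ---------------------------------------------------------------------------

def d_feature_names() -> tuple[list[str], dict[str, str]]:
    """Default D-feature order and subgroup map (computed from a probe)."""
    probe = RnaSequence(id="_probe", residues="AUGGCA" * 12)
    vec = extract_d_features(probe)
    return vec.names, vec.subgroup_of


def extract_d_features(seq: RnaSequence) -> FeatureVector:
    """All descriptor features in a fixed order (default: 753 in 14 subgroups)."""
    blocks: list[tuple[str, dict[str, float]]] = [
        ("orf", orf_features(seq)),
        ("kmer_codon", _kmer_codon_features(seq)),
        ("entropy", _entropy_features(seq)),
        ("autocorrelation", _autocorr_features(seq)),
        ("composition", _composition_features(seq)),
    ]
    s_win = _window(encode(seq))
    pairs = nussinov_pairs(s_win)
    blocks.append(("secondary_structure", structure_features(seq, _pairs=pairs)))
    blocks.append(("eiip_spectrum", eiip_spectrum_features(seq)))
    blocks.append(("structure_graph", _graph_topology_features(seq, pairs)))
    for prop in load_property_registry():
        blocks.append((prop.subgroup, ctd_features(seq, prop)))

    names: list[str] = []
    values: list[float] = []
    subgroup_of: dict[str, str] = {}
    for sub, feats in blocks:
        for n, v in feats.items():
            names.append(n)
            values.append(v)
            subgroup_of[n] = sub
    return FeatureVector(values=np.array(values), names=names,
                         subgroup_of=subgroup_of)


def d_feature_matrix(seqs: list[RnaSequence]) -> tuple[np.ndarray, list[str], dict[str, str]]:
    """Feature matrix (n_sequences x 753) plus names and subgroup map."""
    first = extract_d_features(seqs[0])
    mat = np.empty((len(seqs), len(first)))
    mat[0] = first.values
    for i, s in enumerate(seqs[1:], 1):
        mat[i] = extract_d_features(s).values
    return mat, first.names, first.subgroup_of
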