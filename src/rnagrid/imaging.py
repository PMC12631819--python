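"""Image-like RNA representation: feature templates and rendering.

A template is built once per feature set from a corpus in four steps:
feature-matrix generation (features x sequences), cosine-similarity
calculation among features, 2D embedding of the features with distance
1 - similarity (UMAP by default, classical MDS as a deterministic mode),
and optimal placement of the embedded features onto a rectangular grid by
exact linear assignment.  Each sequence is then rendered as an image by
writing its min-max scaled feature intensities into the template cells.

The grid-sizing rule rows = ceil(sqrt(n)), cols = ceil(n / rows) gives a
28 x 27 grid for the 753 descriptor features and 27 x 27 for the 724
gap features.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from pathlib import Path

import numpy as np
from scipy.optimize import linear_sum_assignment

from . import dfeatures, gfeatures
from .gfeatures import FeatureVector
from .sequences import RnaSequence

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class FeatureTemplate:
    """Bijective feature-name -> grid-cell map with per-feature scaling."""

    feature_set: str                      # "G" or "D"
    grid: tuple[int, int]
    placement: dict[str, tuple[int, int]]
    subgroup_of: dict[str, str]
    scaling: dict[str, tuple[float, float]]
    provenance: dict

    def __post_init__(self) -> None:
        rows, cols = self.grid
        cells = list(self.placement.values())
        if len(set(map(tuple, cells))) != len(cells):
            raise ValueError("placement is not injective")
        if rows * cols < len(self.placement):
            raise ValueError("grid too small for the feature set")
        for name, (lo, hi) in self.scaling.items():
            if hi < lo:
                raise ValueError(f"scaling for {name!r} has max < min")

    @property
    def names(self) -> list[str]:
        return list(self.placement)

    @property
    def subgroups(self) -> list[str]:
        seen: dict[str, None] = {}
        for n in self.placement:
            seen.setdefault(self.subgroup_of[n], None)
        return list(seen)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "format_version": 1,
            "feature_set": self.feature_set,
            "grid": list(self.grid),
            "placement": {k: list(v) for k, v in self.placement.items()},
            "subgroup_of": self.subgroup_of,
            "scaling": {k: list(v) for k, v in self.scaling.items()},
            "provenance": self.provenance,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "FeatureTemplate":
        d = json.loads(Path(path).read_text())
        return cls(
            feature_set=d["feature_set"], grid=tuple(d["grid"]),
            placement={k: tuple(v) for k, v in d["placement"].items()},
            subgroup_of=d["subgroup_of"],
            scaling={k: tuple(v) for k, v in d["scaling"].items()},
            provenance=d["provenance"],
        )


@dataclasses.dataclass
class RnaImagePair:
    """The two rendered intensity grids for one sequence."""

    sequence_id: str
    d_image: np.ndarray
    g_image: np.ndarray


def feature_similarity(matrix: np.ndarray) -> np.ndarray:
    """Cosine similarity among feature rows of a features x sequences matrix.

    Symmetric with unit diagonal.  All-zero feature rows have undefined
    cosine; their off-diagonal similarities are set to 0 with a warning.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need at least 2 features and 2 sequences")
    norms = np.linalg.norm(m, axis=1)
    zero = norms == 0
    if zero.any():
        logger.warning("%d all-zero feature rows: cosine set to 0", zero.sum())
    safe = np.where(zero, 1.0, norms)
    unit = m / safe[:, None]
    sim = np.clip(unit @ unit.T, -1.0, 1.0)
    sim[zero, :] = 0.0
    sim[:, zero] = 0.0
    np.fill_diagonal(sim, 1.0)
    return sim


def grid_dims(n_features: int) -> tuple[int, int]:
    """rows = ceil(sqrt(n)), cols = ceil(n / rows)."""
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    rows = int(np.ceil(np.sqrt(n_features)))
    cols = int(np.ceil(n_features / rows))
    return rows, cols


def assign_to_grid(points: np.ndarray,
                   grid: tuple[int, int]) -> dict[int, tuple[int, int]]:
    """Optimal injective placement of 2D points onto grid cells.

    Points are affinely rescaled to the box spanned by the cell centres; the
    assignment minimising total squared Euclidean distance to cell centres is
    solved exactly (rectangular linear assignment, Jonker-Volgenant family).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be n x 2")
    rows, cols = grid
    n = len(pts)
    if rows * cols < n:
        raise ValueError(f"grid {rows}x{cols} too small for {n} points")
    centers = np.array([(r + 0.5, c + 0.5)
                        for r in range(rows) for c in range(cols)])
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    tgt_lo, tgt_hi = centers.min(axis=0), centers.max(axis=0)
    scaled = tgt_lo + (pts - lo) / span * (tgt_hi - tgt_lo)
    cost = ((scaled[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    ri, ci = linear_sum_assignment(cost)
    order = np.argsort(ri)
    return {int(ri[t]): (int(centers[ci[t], 0] - 0.5), int(centers[ci[t], 1] - 0.5))
            for t in order}


def _classical_mds(dist: np.ndarray, n_components: int = 2) -> np.ndarray:
    """Classical MDS (principal-coordinates) embedding of a distance matrix."""
    n = dist.shape[0]
    d2 = dist ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    w, v = np.linalg.eigh(B)
    idx = np.argsort(w)[::-1][:n_components]
    w_top = np.clip(w[idx], 0.0, None)
    return v[:, idx] * np.sqrt(w_top)


def embed_features(similarity: np.ndarray, method: str = "umap",
                   seed: int = 0, **umap_kwargs) -> np.ndarray:
    """2D embedding of features from their similarity matrix.

    Distance is 1 - similarity.  ``method='umap'`` (default) uses a manifold
    embedding with a fixed random state; ``method='mds'`` is classical
    multidimensional scaling, fully deterministic and dependency-light, used
    in the test suite.
    """
    dist = np.clip(1.0 - similarity, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    if method == "mds":
        return _classical_mds(dist)
    if method == "umap":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            import umap
            reducer = umap.UMAP(n_components=2, metric="precomputed",
                                random_state=seed, **umap_kwargs)
            return np.asarray(reducer.fit_transform(dist), dtype=float)
    raise ValueError(f"unknown embedding method {method!r}")


def build_template(corpus: list[RnaSequence], feature_set: str,
                   method: str = "umap", seed: int = 0,
                   **embed_kwargs) -> FeatureTemplate:
    """Build a feature template from a corpus.

    Pipeline: extract the feature matrix for all sequences, compute the
    feature-feature cosine similarity, embed the features in 2D, choose grid
    dimensions by the sizing rule, and place features on the grid by exact
    linear assignment.  Per-feature min/max scaling is fit on the corpus.
    """
    if len(corpus) < 10:
        raise ValueError("template corpus must have at least 10 sequences")
    if feature_set == "G":
        mat, names, subgroup_of = gfeatures.g_feature_matrix(corpus)
    elif feature_set == "D":
        mat, names, subgroup_of = dfeatures.d_feature_matrix(corpus)
    else:
        raise ValueError("feature_set must be 'G' or 'D'")
    sim = feature_similarity(mat.T)  # rows = features
    points = embed_features(sim, method=method, seed=seed, **embed_kwargs)
    grid = grid_dims(len(names))
    cells = assign_to_grid(points, grid)
    placement = {name: cells[i] for i, name in enumerate(names)}
    scaling = {name: (float(mat[:, i].min()), float(mat[:, i].max()))
               for i, name in enumerate(names)}
    return FeatureTemplate(
        feature_set=feature_set, grid=grid, placement=placement,
        subgroup_of=subgroup_of, scaling=scaling,
        provenance={"corpus_size": len(corpus), "seed": seed,
                    "embedding": method, "embedding_params": embed_kwargs},
    )


def render_image(vector: FeatureVector, template: FeatureTemplate) -> np.ndarray:
    """Render one feature vector onto the template grid.

    Cell intensity is the feature value min-max scaled by the template's
    training range, clipped to [0, 1]; constant features render as 0, and
    cells without a feature stay exactly 0.
    """
    tnames = set(template.placement)
    vnames = set(vector.names)
    if tnames != vnames:
        missing = sorted(tnames - vnames)[:5]
        extra = sorted(vnames - tnames)[:5]
        raise ValueError(
            f"feature names do not match template (missing {missing}, "
            f"extra {extra})")
    img = np.zeros(template.grid, dtype=float)
    for name, value in zip(vector.names, vector.values):
        lo, hi = template.scaling[name]
        r, c = template.placement[name]
        img[r, c] = np.clip((value - lo) / (hi - lo), 0.0, 1.0) if hi > lo else 0.0
    return img


def split_channels(image: np.ndarray, template: FeatureTemplate) -> np.ndarray:
    """Split an image into per-subgroup channels (rows x cols x n_subgroups).

    Each channel keeps only its subgroup's cells; the element-wise sum of all
    channels reproduces the input image exactly.
    """
    subs = template.subgroups
    out = np.zeros(template.grid + (len(subs),), dtype=image.dtype)
    sub_index = {s: i for i, s in enumerate(subs)}
    for name, (r, c) in template.placement.items():
        out[r, c, sub_index[template.subgroup_of[name]]] = image[r, c]
    return out


def render_pair(seq: RnaSequence, template_d: FeatureTemplate,
                template_g: FeatureTemplate) -> RnaImagePair:
    """Render both images for one sequence."""
    return RnaImagePair(
        sequence_id=seq.id,
        d_image=render_image(dfeatures.extract_d_features(seq), template_d),
        g_image=render_image(gfeatures.extract_g_features(seq), template_g),
    )


def render_corpus_channels(
    seqs: list[RnaSequence], template_d: FeatureTemplate,
    template_g: FeatureTemplate,
    d_matrix: np.ndarray | None = None, g_matrix: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Channel stacks for a corpus: (n, 28, 27, n_d_subs), (n, 27, 27, n_g_subs).

    Pre-extracted feature matrices may be passed to avoid recomputation.
    """
    if d_matrix is None:
        d_matrix, _, _ = dfeatures.d_feature_matrix(seqs)
    if g_matrix is None:
        g_matrix, _, _ = gfeatures.g_feature_matrix(seqs)
    d_names, d_sub = dfeatures.d_feature_names()
    g_names, g_sub = gfeatures.g_feature_names()
    n = len(seqs)
    d_out = np.zeros((n,) + template_d.grid + (len(template_d.subgroups),),
                     dtype=np.float32)
    g_out = np.zeros((n,) + template_g.grid + (len(template_g.subgroups),),
                     dtype=np.float32)
    for i in range(n):
        dv = FeatureVector(d_matrix[i], d_names, d_sub)
        gv = FeatureVector(g_matrix[i], g_names, g_sub)
        d_out[i] = split_channels(render_image(dv, template_d), template_d)
        g_out[i] = split_channels(render_image(gv, template_g), template_g)
    return d_out, g_out
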