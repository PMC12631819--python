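"""Gap-based G-features: ordered nucleotide-pair counts at fixed gaps.

A feature ``k-XY`` counts positions ``i`` (1-based) with ``residue(i) == X``
and ``residue(i + k + 1) == Y`` — i.e. the ordered pair X..Y with exactly
``k`` residues strictly between them.  The default feature set spans gaps
0..40 for all 16 ordered pairs (656 features in 16 per-pair subgroups) plus a
17th composition subgroup of 4 mononucleotide and 64 trinucleotide counts,
724 features in 17 subgroups in total.

Counts are raw (not length-normalised); scaling to image intensities is done
by the imaging stage when a template is applied.
"""

from __future__ import annotations

import dataclasses
import re

import numpy as np

from .sequences import RNA_ALPHABET, RnaSequence

MAX_GAP_DEFAULT = 40
ORDERED_PAIRS = tuple(x + y for x in RNA_ALPHABET for y in RNA_ALPHABET)
COMPOSITION_SUBGROUP = "composition"

_NAME_RE = re.compile(r"^(\d+)-([ACGU])([ACGU])$")

_BASE_INDEX = {b: i for i, b in enumerate(RNA_ALPHABET)}


@dataclasses.dataclass(frozen=True)
class GapFeatureSpec:
    """An ordered nucleotide pair with a fixed gap, e.g. ``2-GC``."""

    first: str
    second: str
    gap: int

    def __post_init__(self) -> None:
        if self.first not in RNA_ALPHABET or self.second not in RNA_ALPHABET:
            raise ValueError("first/second must be single RNA bases")
        if self.gap < 0:
            raise ValueError("gap must be >= 0")

    @property
    def name(self) -> str:
        return f"{self.gap}-{self.first}{self.second}"

    @classmethod
    def from_name(cls, name: str) -> "GapFeatureSpec":
        m = _NAME_RE.match(name)
        if not m:
            raise ValueError(f"not a canonical gap-feature name: {name!r}")
        return cls(first=m.group(2), second=m.group(3), gap=int(m.group(1)))


@dataclasses.dataclass
class FeatureVector:
    """A named, subgroup-annotated numeric feature vector."""

    values: np.ndarray
    names: list[str]
    subgroup_of: dict[str, str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.names),):
            raise ValueError("values/names length mismatch")

    def __len__(self) -> int:
        return len(self.names)

    @property
    def subgroups(self) -> list[str]:
        """Distinct subgroup ids in first-appearance order."""
        seen: dict[str, None] = {}
        for n in self.names:
            seen.setdefault(self.subgroup_of[n], None)
        return list(seen)


def encode(seq: RnaSequence) -> np.ndarray:
    """Residues as an int array (A=0, C=1, G=2, U=3)."""
    return np.frombuffer(
        seq.residues.translate(str.maketrans("ACGU", "\x00\x01\x02\x03"))
        .encode("latin1"), dtype=np.uint8).astype(np.int64)


def count_gap_pair(seq: RnaSequence, spec: GapFeatureSpec) -> int:
    """Count occurrences of the ordered pair at the spec's gap."""
    k = spec.gap
    s = encode(seq)
    if len(s) <= k + 1:
        return 0
    a, b = _BASE_INDEX[spec.first], _BASE_INDEX[spec.second]
    return int(np.count_nonzero((s[: len(s) - k - 1] == a) & (s[k + 1:] == b)))


def g_feature_names(max_gap: int = MAX_GAP_DEFAULT) -> tuple[list[str], dict[str, str]]:
    """Default feature order and subgroup map (pairs first, then composition)."""
    names: list[str] = []
    subgroup: dict[str, str] = {}
    for pair in ORDERED_PAIRS:
        for k in range(max_gap + 1):
            name = f"{k}-{pair}"
            names.append(name)
            subgroup[name] = f"pair-{pair}"
    for b in RNA_ALPHABET:
        name = f"mono-{b}"
        names.append(name)
        subgroup[name] = COMPOSITION_SUBGROUP
    for t in (x + y + z for x in RNA_ALPHABET for y in RNA_ALPHABET
              for z in RNA_ALPHABET):
        name = f"tri-{t}"
        names.append(name)
        subgroup[name] = COMPOSITION_SUBGROUP
    return names, subgroup


def extract_g_features(seq: RnaSequence,
                       max_gap: int = MAX_GAP_DEFAULT) -> FeatureVector:
    """All gap-pair counts plus the composition subgroup, in a fixed order.

    The default configuration emits 724 features in 17 subgroups.
    """
    s = encode(seq)
    L = len(s)
    values = np.empty(16 * (max_gap + 1) + 4 + 64, dtype=float)
    # gap-pair block: for each gap, one vectorised bincount over pair codes
    counts = np.zeros((16, max_gap + 1), dtype=float)
    for k in range(max_gap + 1):
        if L <= k + 1:
            break
        codes = s[: L - k - 1] * 4 + s[k + 1:]
        counts[:, k] = np.bincount(codes, minlength=16)
    values[: 16 * (max_gap + 1)] = counts.reshape(-1)
    off = 16 * (max_gap + 1)
    values[off: off + 4] = np.bincount(s, minlength=4)
    if L >= 3:
        tri = s[:-2] * 16 + s[1:-1] * 4 + s[2:]
        values[off + 4:] = np.bincount(tri, minlength=64)
    else:
        values[off + 4:] = 0.0
    names, subgroup = g_feature_names(max_gap)
    return FeatureVector(values=values, names=names, subgroup_of=subgroup)


def g_feature_matrix(seqs: list[RnaSequence],
                     max_gap: int = MAX_GAP_DEFAULT) -> tuple[np.ndarray, list[str], dict[str, str]]:
    """Feature matrix (n_sequences x n_features) plus names and subgroups."""
    names, subgroup = g_feature_names(max_gap)
    mat = np.empty((len(seqs), len(names)))
    for i, s in enumerate(seqs):
        mat[i] = extract_g_features(s, max_gap).values
    return mat, names, subgroup
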