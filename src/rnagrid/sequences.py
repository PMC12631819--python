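"""Sequence I/O, validation and synthetic labeled-corpus generation.

RNA sequences are held as validated strings over {A, C, G, U}.  DNA input is
accepted everywhere and silently normalised (T -> U, lowercase -> uppercase),
since most public transcript collections ship DNA-alphabet sequences.

The synthetic corpus generator produces labeled toy datasets for the three
classification tasks supported downstream (coding potential, k-class small-RNA
taxonomy, circular vs linear), so the whole pipeline can be exercised and
tested without any external download.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

RNA_ALPHABET = "ACGU"
#: IUPAC degenerate codes and the unambiguous RNA bases they stand for.
IUPAC_DEGENERATE = {
    "N": "ACGU", "R": "AG", "Y": "CU", "S": "CG", "W": "AU",
    "K": "GU", "M": "AC", "B": "CGU", "D": "AGU", "H": "ACU", "V": "ACG",
}

DegeneratePolicy = Literal["reject", "drop-record", "map-random"]


class FastaParseError(ValueError):
    """Raised for malformed FASTA records or disallowed residues."""


class DegenerateBaseError(FastaParseError):
    """Raised under the 'reject' policy when a degenerate base is found."""


@dataclasses.dataclass(frozen=True)
class RnaSequence:
    """A validated RNA sequence with an identifier.

    ``residues`` contains only A/C/G/U after normalisation; ``length`` is the
    residue count (>= 1).
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - set(RNA_ALPHABET)
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains non-ACGU residues: {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.residues)


@dataclasses.dataclass
class LabeledCorpus:
    """A list of sequences plus an id -> class-label map."""

    sequences: list[RnaSequence]
    labels: dict[str, str]
    classes: list[str]

    def __post_init__(self) -> None:
        ids = [s.id for s in self.sequences]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sequence ids in corpus")
        missing = [i for i in ids if i not in self.labels]
        if missing:
            raise ValueError(f"sequences without labels: {missing[:5]}")
        if len(self.classes) < 2:
            raise ValueError("a training corpus needs at least 2 classes")

    def __len__(self) -> int:
        return len(self.sequences)

    def y(self) -> np.ndarray:
        """Integer class index per sequence, in ``classes`` order."""
        index = {c: k for k, c in enumerate(self.classes)}
        return np.array([index[self.labels[s.id]] for s in self.sequences])


def normalize_residues(raw: str) -> str:
    """Uppercase and convert the DNA alphabet to RNA (T -> U)."""
    return raw.upper().replace("T", "U")


def _resolve_degenerate(residues: str, rec_id: str, policy: DegeneratePolicy,
                        rng: np.random.Generator | None) -> str | None:
    """Apply the degenerate-base policy; None means drop the record."""
    degenerate = [b for b in residues if b not in RNA_ALPHABET]
    if not degenerate:
        return residues
    unknown = [b for b in degenerate if b not in IUPAC_DEGENERATE]
    if unknown:
        raise FastaParseError(
            f"record {rec_id!r}: non-IUPAC characters {sorted(set(unknown))}"
        )
    if policy == "reject":
        raise DegenerateBaseError(
            f"record {rec_id!r} contains degenerate bases "
            f"{sorted(set(degenerate))} (policy=reject)"
        )
    if policy == "drop-record":
        return None
    if policy == "map-random":
        if rng is None:
            raise ValueError("policy 'map-random' requires a seed")
        out = [
            b if b in RNA_ALPHABET
            else IUPAC_DEGENERATE[b][rng.integers(len(IUPAC_DEGENERATE[b]))]
            for b in residues
        ]
        return "".join(out)
    raise ValueError(f"unknown degenerate-base policy {policy!r}")


def read_fasta(path: str | Path, policy: DegeneratePolicy = "reject",
               seed: int | None = None) -> list[RnaSequence]:
    """Read a (multi-record) FASTA file into normalised RNA sequences.

    Record order is preserved.  Degenerate IUPAC bases are handled per
    ``policy``: ``reject`` (default) raises naming the record, ``drop-record``
    silently skips the record, ``map-random`` replaces each degenerate base by
    a uniform choice among the bases it denotes (seeded).
    """
    rng = np.random.default_rng(seed) if seed is not None else None
    out: list[RnaSequence] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = normalize_residues(str(rec.seq))
        if not residues:
            raise FastaParseError(f"record {rec.id!r} has an empty sequence")
        resolved = _resolve_degenerate(residues, rec.id, policy, rng)
        if resolved is None:
            continue
        out.append(RnaSequence(id=rec.id, residues=resolved))
    return out


def write_fasta(sequences: Iterable[RnaSequence], path: str | Path,
                width: int = 60) -> None:
    """Write sequences to FASTA (wrapped at ``width`` columns)."""
    records = [SeqRecord(Seq(s.residues), id=s.id, description="")
               for s in sequences]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
    del width  # Biopython's fasta writer wraps at 60 columns


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a 2-column TSV (id<TAB>label) into a dict."""
    labels: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{ln}: expected 2 tab-separated fields")
            labels[parts[0]] = parts[1]
    return labels


def write_labels(labels: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, lab in labels.items():
            fh.write(f"{sid}\t{lab}\n")


# ---------------------------------------------------------------------------
# Synthetic corpus generation
# ---------------------------------------------------------------------------

_STOP_CODONS = ("UAA", "UAG", "UGA")
_SENSE_CODONS = tuple(
    a + b + c
    for a in RNA_ALPHABET for b in RNA_ALPHABET for c in RNA_ALPHABET
    if a + b + c not in _STOP_CODONS
)
# Stylised codon-usage bias: GC-ending codons favoured 3:1, a crude stand-in
# for the codon-preference signal real coding regions carry.
_CODON_WEIGHTS = np.array(
    [3.0 if c[2] in "GC" else 1.0 for c in _SENSE_CODONS]
)
_CODON_WEIGHTS /= _CODON_WEIGHTS.sum()


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list(RNA_ALPHABET))[rng.integers(0, 4, n)])


def _coding_like(rng: np.random.Generator, length: int) -> str:
    """A sequence with an embedded in-frame ORF covering >= 50% of it.

    The ORF is AUG + biased sense codons + a stop, so the reading frame is
    stop-free by construction and the planted ORF is itself an open reading
    frame of length >= ceil(L/2) rounded up to a codon multiple.
    """
    min_orf = int(np.ceil(length / 2))
    frac = rng.uniform(0.55, 0.85)
    n_codons = max(int(length * frac) // 3, -(-min_orf // 3))
    n_codons = min(n_codons, length // 3)
    orf_len = 3 * n_codons
    inner = rng.choice(len(_SENSE_CODONS), size=n_codons - 2, p=_CODON_WEIGHTS)
    orf = "AUG" + "".join(_SENSE_CODONS[i] for i in inner) + \
        _STOP_CODONS[rng.integers(3)]
    start = rng.integers(0, length - orf_len + 1)
    return _random_bases(rng, start) + orf + _random_bases(
        rng, length - orf_len - start)


def dinucleotide_shuffle(residues: str, rng: np.random.Generator) -> str:
    """Shuffle a sequence preserving all 16 dinucleotide counts exactly.

    Altschul–Erickson construction: view the sequence as an Eulerian walk on
    the 4-vertex dinucleotide multigraph, draw a random last-exit edge per
    vertex until those edges form a tree into the final vertex, shuffle the
    remaining out-edges, and rebuild the walk.  First and last residues are
    preserved, hence so is every dinucleotide count.
    """
    if len(residues) < 3:
        return residues
    s = residues
    first, last = s[0], s[-1]
    out_edges: dict[str, list[str]] = {b: [] for b in RNA_ALPHABET}
    for x, y in zip(s, s[1:]):
        out_edges[x].append(y)
    vertices = [b for b in RNA_ALPHABET if out_edges[b] or b == last]

    def reaches_last(last_exit: dict[str, str]) -> bool:
        for v in vertices:
            seen, cur = set(), v
            while cur != last and cur in last_exit and cur not in seen:
                seen.add(cur)
                cur = last_exit[cur]
            if cur != last:
                return False
        return True

    while True:
        last_exit = {
            v: out_edges[v][rng.integers(len(out_edges[v]))]
            for v in vertices if v != last and out_edges[v]
        }
        if reaches_last(last_exit):
            break

    pools: dict[str, list[str]] = {}
    for v in vertices:
        pool = list(out_edges[v])
        if v in last_exit:
            pool.remove(last_exit[v])
        rng.shuffle(pool)
        if v in last_exit:
            pool.append(last_exit[v])
        pools[v] = pool

    walk = [first]
    idx = {v: 0 for v in vertices}
    cur = first
    for _ in range(len(s) - 1):
        nxt = pools[cur][idx[cur]]
        idx[cur] += 1
        walk.append(nxt)
        cur = nxt
    return "".join(walk)


def _plant_motifs(rng: np.random.Generator, length: int,
                  motifs: Sequence[str], density: float) -> str:
    """IID background with motifs planted at about one per 1/density nt."""
    seq = list(_random_bases(rng, length))
    n_sites = max(1, int(length * density))
    for _ in range(n_sites):
        m = motifs[rng.integers(len(motifs))]
        pos = rng.integers(0, length - len(m) + 1)
        seq[pos:pos + len(m)] = m
    return "".join(seq)


def generate_synthetic_corpus(
    n_per_class: int,
    task: str = "coding",
    length_range: tuple[int, int] = (300, 600),
    seed: int = 0,
    k: int = 3,
    motif_density: float = 1 / 80,
) -> LabeledCorpus:
    """Generate a labeled synthetic corpus for one of the three tasks.

    ``task='coding'``: the coding-like class carries an embedded in-frame ORF
    covering >= 50% of the sequence with codon-usage bias; each noncoding-like
    sequence is a dinucleotide-preserving shuffle of its coding-like partner
    (destroys the ORF/periodicity signal, preserves composition exactly).

    ``task='taxonomy'``: ``k`` classes, each with three class-specific planted
    8-mer motifs at ``motif_density`` occurrences per nucleotide.

    ``task='circular-linear'``: the circular-like class is enriched for a
    stylised back-splice junction motif; the linear-like class is IID.

    Deterministic for a fixed seed.
    """
    lo, hi = length_range
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if lo < 60:
        raise ValueError("minimum length must be >= 60 (ORF planting)")
    if hi < lo:
        raise ValueError("length_range must be (min, max) with max >= min")
    rng = np.random.default_rng(seed)

    sequences: list[RnaSequence] = []
    labels: dict[str, str] = {}

    def add(sid: str, residues: str, label: str) -> None:
        sequences.append(RnaSequence(id=sid, residues=residues))
        labels[sid] = label

    if task == "coding":
        classes = ["coding-like", "noncoding-like"]
        for i in range(n_per_class):
            length = int(rng.integers(lo, hi + 1))
            pos = _coding_like(rng, length)
            add(f"coding_{i:04d}", pos, classes[0])
            add(f"noncoding_{i:04d}", dinucleotide_shuffle(pos, rng),
                classes[1])
    elif task == "taxonomy":
        if k < 2:
            raise ValueError("taxonomy task needs k >= 2 classes")
        classes = [f"family_{c + 1}" for c in range(k)]
        motif_sets = []
        seen: set[str] = set()
        for _ in range(k):
            motifs = []
            while len(motifs) < 3:
                m = _random_bases(rng, 8)
                if m not in seen:
                    seen.add(m)
                    motifs.append(m)
            motif_sets.append(motifs)
        for c, label in enumerate(classes):
            for i in range(n_per_class):
                length = int(rng.integers(lo, hi + 1))
                add(f"{label}_{i:04d}",
                    _plant_motifs(rng, length, motif_sets[c], motif_density),
                    label)
    elif task == "circular-linear":
        classes = ["circular-like", "linear-like"]
        junction = ("GUAAGUAG",)
        for i in range(n_per_class):
            length = int(rng.integers(lo, hi + 1))
            add(f"circ_{i:04d}",
                _plant_motifs(rng, length, junction, motif_density),
                classes[0])
            length = int(rng.integers(lo, hi + 1))
            add(f"lin_{i:04d}", _random_bases(rng, length), classes[1])
    else:
        raise ValueError(f"unknown task {task!r}")

    return LabeledCorpus(sequences=sequences, labels=labels, classes=classes)
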