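"""iPWM bit-scoring of promoter sequences and thresholded site discovery.

An information-theory PWM (iPWM) stores per-position, per-base weights in
bits; the score of a k-mer — the sum of the weights along it — is the site's
individual information R_i.  R_sequence, the matrix's average information
content (area under the sequence logo), sets both the site-level scan
threshold (0.1 x R_sequence) and the "strong site" criterion
(R_i > R_sequence) used downstream.

Scanning slides the matrix over both strands of every accessible subinterval
of a promoter (the 10 kb region upstream of the TSS, optionally intersected
with DNase I hypersensitive sites) and keeps windows whose R_i meets the
threshold.  Windows containing non-ACGT characters are skipped rather than
scored with fabricated weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .formats import (
    GenomicInterval,
    get_sequence,
    iPWMFile,
    merge_intervals,
    reverse_complement,
)

__all__ = [
    "BASES",
    "iPWM",
    "BindingSite",
    "Promoter",
    "encode",
    "score_site",
    "matrix_r_sequence",
    "make_promoter",
    "restrict_to_accessible",
    "scan",
]

BASES = "ACGT"
_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def encode(seq: str) -> np.ndarray:
    """Map a DNA string to int codes A=0 C=1 G=2 T=3; anything else -> 4."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class iPWM:
    """In-memory iPWM: ``weights[j, b]`` in bits, base order A,C,G,T."""

    tf: str
    weights: np.ndarray
    cell_line: str = ""
    r_sequence_meta: float | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[1] != 4 or w.shape[0] < 1:
            raise ValueError(f"weights must be width x 4, got {w.shape}")
        self.weights = w

    @classmethod
    def from_file(cls, f: iPWMFile) -> "iPWM":
        return cls(tf=f.tf, weights=f.weights, cell_line=f.cell_line,
                   r_sequence_meta=f.r_sequence_meta)

    def to_file(self) -> iPWMFile:
        return iPWMFile(tf=self.tf, cell_line=self.cell_line,
                        weights=self.weights, r_sequence_meta=self.r_sequence_meta)

    @property
    def width(self) -> int:
        return self.weights.shape[0]

    @property
    def r_sequence(self) -> float:
        return matrix_r_sequence(self)

    @property
    def consensus(self) -> str:
        return "".join(BASES[b] for b in np.argmax(self.weights, axis=1))

    @property
    def max_score(self) -> float:
        return float(self.weights.max(axis=1).sum())


@dataclass(frozen=True)
class BindingSite:
    """A scored motif occurrence.  ``sequence`` is the motif-strand k-mer."""

    tf: str
    contig: str
    start: int
    strand: str
    sequence: str
    r_i: float

    @property
    def width(self) -> int:
        return len(self.sequence)

    @property
    def end(self) -> int:
        return self.start + len(self.sequence)

    @property
    def center(self) -> int:
        # start + floor(L/2): symmetric under strand
        return self.start + len(self.sequence) // 2


@dataclass
class Promoter:
    """A gene's promoter interval with its accessible subintervals.

    ``accessible`` lists the (merged, sorted) subintervals actually scanned;
    by default it is the whole promoter (accessibility masking disabled).
    """

    gene_id: str
    contig: str
    tss: int
    strand: str
    interval: GenomicInterval
    accessible: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.accessible:
            self.accessible = [self.interval]
        prev_end = None
        for iv in self.accessible:
            if iv.contig != self.contig:
                raise ValueError("accessible interval on wrong contig")
            if iv.start < self.interval.start or iv.end > self.interval.end:
                raise ValueError("accessible interval outside promoter")
            if prev_end is not None and iv.start < prev_end:
                raise ValueError("accessible intervals must be sorted, non-overlapping")
            prev_end = iv.end


def score_site(m: iPWM, kmer: str) -> float:
    """R_i of a k-mer in bits: the sum of the matrix weights along it."""
    if len(kmer) != m.width:
        raise ValueError(f"k-mer length {len(kmer)} != matrix width {m.width}")
    code = encode(kmer)
    if np.any(code > 3):
        raise ValueError(f"k-mer contains non-ACGT characters: {kmer!r}")
    return float(m.weights[np.arange(m.width), code].sum())


def matrix_r_sequence(m: iPWM) -> float:
    """R_sequence in bits: file metadata if present, else recomputed.

    Recomputation assumes the weights derive from a base-frequency matrix f
    via ``w = 2 + log2 f`` and returns ``sum_j (2 + sum_b f log2 f)``.  Columns
    are renormalized to absorb the floor applied to near-zero frequencies.
    """
    if m.r_sequence_meta is not None:
        return float(m.r_sequence_meta)
    w = m.weights
    if np.any(w > 2.0 + 1e-9):
        raise ValueError(
            f"{m.tf}: weights exceed 2 bits; frequencies unrecoverable and no "
            "R_sequence metadata present"
        )
    f = np.power(2.0, w - 2.0)
    sums = f.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 0.05):
        raise ValueError(f"{m.tf}: recovered frequencies do not sum to 1 per column")
    f = f / sums[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(f > 0, f * np.log2(np.where(f > 0, f, 1.0)), 0.0)
    return float(np.sum(2.0 + plogp.sum(axis=1)))


def make_promoter(
    gene_id: str,
    contig: str,
    tss: int,
    strand: str,
    contig_length: int,
    length: int = 10_000,
) -> Promoter:
    """The promoter interval up to ``length`` bp strictly upstream of the TSS.

    '+' genes: ``[max(0, tss - length), tss)``; '-' genes:
    ``[tss, min(contig_length, tss + length))``; clamped at contig bounds.
    """
    if not (0 <= tss <= contig_length):
        raise ValueError(f"TSS {tss} outside contig of length {contig_length}")
    if strand == "+":
        start, end = max(0, tss - length), tss
    elif strand == "-":
        start, end = tss, min(contig_length, tss + length)
    else:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    if start >= end:
        raise ValueError(f"gene {gene_id}: promoter is empty (TSS at contig edge)")
    return Promoter(gene_id, contig, tss, strand, GenomicInterval(contig, start, end))


def restrict_to_accessible(
    p: Promoter, dhs: Iterable[GenomicInterval]
) -> Promoter:
    """Promoter with accessibility masking: scan only promoter ∩ DHS.

    The accessible set is the merged union of the promoter's intersections
    with each DHS; it may be empty (then scanning yields no sites).
    """
    pieces = [
        x for iv in dhs if (x := p.interval.intersect(iv)) is not None
    ]
    merged = merge_intervals(pieces) if pieces else []
    q = Promoter(p.gene_id, p.contig, p.tss, p.strand, p.interval)
    q.accessible = merged
    return q


def scan(
    m: iPWM,
    promoter: Promoter,
    genome,
    threshold_frac: float = 0.1,
    r_sequence: float | None = None,
) -> list[BindingSite]:
    """All binding sites of ``m`` in the promoter's accessible intervals.

    Both strands are scanned; a window is kept when its R_i is at least
    ``threshold_frac * R_sequence``.  Sites lie fully inside one accessible
    subinterval.  Output is sorted by start, then strand ('+' before '-').
    Overlapping and palindromic (both-strand) hits are all retained.
    """
    rs = float(r_sequence) if r_sequence is not None else m.r_sequence
    thr = threshold_frac * rs
    L = m.width
    W = m.weights
    Wrc = W[::-1, ::-1]  # scoring the revcomp of a forward window
    pos_idx = np.arange(L)
    sites: list[BindingSite] = []
    for iv in promoter.accessible:
        if iv.length < L:
            continue
        seq = get_sequence(genome, iv, "+")
        code = encode(seq)
        n = len(code) - L + 1
        windows = code[np.arange(n)[:, None] + pos_idx[None, :]]
        ok = ~(windows > 3).any(axis=1)
        safe = np.where(windows > 3, 0, windows)
        fwd = W[pos_idx[None, :], safe].sum(axis=1)
        rev = Wrc[pos_idx[None, :], safe].sum(axis=1)
        for i in np.nonzero(ok & (fwd >= thr))[0]:
            sites.append(BindingSite(m.tf, iv.contig, iv.start + int(i), "+",
                                     seq[i : i + L], float(fwd[i])))
        for i in np.nonzero(ok & (rev >= thr))[0]:
            sites.append(BindingSite(m.tf, iv.contig, iv.start + int(i), "-",
                                     reverse_complement(seq[i : i + L]), float(rev[i])))
    sites.sort(key=lambda s: (s.start, 0 if s.strand == "+" else 1))
    return sites
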