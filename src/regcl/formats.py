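"""Readers and writers for the plain-text formats the pipeline exchanges.

Coordinate contract
-------------------
All genomic coordinates inside the package are 0-based, half-open
(``[start, end)``), the BED convention.  Variant input is 1-based (the
VCF/dbSNP convention); :func:`to_zero_based` is the single place where the
conversion happens.

File dialects
-------------
iPWM
    One header line ``tf<TAB>cell_line[<TAB>r_sequence]`` followed by one
    whitespace-separated row of four reals (bits; base order A, C, G, T) per
    motif position.  Writing uses ``repr`` so matrices round-trip bit-exactly.
BED
    BED3+; columns beyond the third are ignored on input.
Tables
    TSV with one header row (tissue / guide names) and one row per gene.
"""

from __future__ import annotations

import math
from bisect import bisect_left
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .expression import ExpressionMatrix

__all__ = [
    "FormatError",
    "GenomicInterval",
    "iPWMFile",
    "KnockdownMatrix",
    "PValueTable",
    "read_ipwm",
    "write_ipwm",
    "read_bed",
    "write_bed",
    "read_expression_table",
    "read_guide_coefficients",
    "read_pvalue_table",
    "read_tss_table",
    "get_sequence",
    "reverse_complement",
    "merge_intervals",
    "to_zero_based",
]


class FormatError(ValueError):
    """A malformed record in an input file; the message names the location."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval ``[start, end)`` on a named contig."""

    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.contig:
            raise ValueError("contig must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.contig}:[{self.start},{self.end}): "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )

    def intersect(self, other: "GenomicInterval") -> "GenomicInterval | None":
        if not self.overlaps(other):
            return None
        return GenomicInterval(
            self.contig, max(self.start, other.start), min(self.end, other.end)
        )


@dataclass
class iPWMFile:
    """An information-theory PWM as stored on disk.

    ``weights[j, b]`` is the bit weight of base ``ACGT[b]`` at motif position
    ``j``; summing weights along a k-mer yields that site's R_i.
    ``r_sequence_meta`` optionally records the matrix's average information
    content (R_sequence, bits) as metadata.
    """

    tf: str
    cell_line: str
    weights: np.ndarray
    r_sequence_meta: float | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[1] != 4 or w.shape[0] < 1:
            raise ValueError(f"weights must be width x 4, got shape {w.shape}")
        if not np.all(np.isfinite(w)):
            raise ValueError("weights must be finite")
        self.weights = w

    @property
    def width(self) -> int:
        return self.weights.shape[0]


@dataclass
class KnockdownMatrix:
    """Genes x guides matrix of CRISPR guide coefficients (log10 fold change)."""

    genes: list[str]
    guides: list[str]
    coefficients: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.coefficients, dtype=float)
        if c.shape != (len(self.genes), len(self.guides)):
            raise ValueError(
                f"coefficient shape {c.shape} does not match "
                f"{len(self.genes)} genes x {len(self.guides)} guides"
            )
        if not np.all(np.isfinite(c)):
            raise ValueError("coefficients must be finite")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene ids")
        self.coefficients = c

    def row(self, gene: str) -> np.ndarray:
        return self.coefficients[self.genes.index(gene)]


@dataclass
class PValueTable:
    """Per-gene knockdown differential-expression p-values."""

    pvalues: dict[str, float]

    def __post_init__(self) -> None:
        for gene, p in self.pvalues.items():
            if not (0.0 <= p <= 1.0) or math.isnan(p):
                raise ValueError(f"p-value for {gene} outside [0,1]: {p}")


# ---------------------------------------------------------------------------
# iPWM dialect
# ---------------------------------------------------------------------------

def read_ipwm(path: str | Path) -> iPWMFile:
    """Parse the iPWM text dialect (see module docstring)."""
    lines = Path(path).read_text().splitlines()
    body = [(i + 1, ln) for i, ln in enumerate(lines) if ln.strip()]
    if not body:
        raise FormatError(f"{path}: empty iPWM file")
    lineno, header = body[0]
    fields = header.rstrip("\n").split("\t")
    if len(fields) not in (2, 3):
        raise FormatError(
            f"{path}:{lineno}: header must be 'tf<TAB>cell_line[<TAB>r_sequence]'"
        )
    r_meta: float | None = None
    if len(fields) == 3:
        try:
            r_meta = float(fields[2])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: bad r_sequence {fields[2]!r}") from exc
    rows = []
    for lineno, ln in body[1:]:
        cols = ln.split()
        if len(cols) != 4:
            raise FormatError(f"{path}:{lineno}: expected 4 columns, got {len(cols)}")
        try:
            rows.append([float(c) for c in cols])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric weight") from exc
    if not rows:
        raise FormatError(f"{path}: iPWM has no weight rows")
    return iPWMFile(tf=fields[0], cell_line=fields[1], weights=np.array(rows), r_sequence_meta=r_meta)


def write_ipwm(m: iPWMFile, path: str | Path) -> None:
    """Write an iPWM so that :func:`read_ipwm` round-trips it bit-exactly."""
    header = [m.tf, m.cell_line]
    if m.r_sequence_meta is not None:
        header.append(repr(float(m.r_sequence_meta)))
    out = ["\t".join(header)]
    for row in m.weights:
        out.append("\t".join(repr(float(v)) for v in row))
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[GenomicInterval]:
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            try:
                intervals.append(GenomicInterval(cols[0], start, end))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\n")


def merge_intervals(
    intervals: Iterable[GenomicInterval], adjacent: bool = True
) -> list[GenomicInterval]:
    """Coalesce overlapping (and, by default, book-ended) intervals per contig."""
    by_contig: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_contig.setdefault(iv.contig, []).append(iv)
    merged: list[GenomicInterval] = []
    for contig in sorted(by_contig):
        ivs = sorted(by_contig[contig], key=lambda i: (i.start, i.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            joins = iv.start <= cur_end if adjacent else iv.start < cur_end
            if joins:
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(contig, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(GenomicInterval(contig, cur_start, cur_end))
    return merged


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def _read_tsv_matrix(path: str | Path, what: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate gene id {dup!r}")
    try:
        out = df.apply(lambda col: pd.to_numeric(col, errors="raise"))
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: non-numeric cell in {what} table: {exc}") from exc
    return out


def read_expression_table(path: str | Path) -> "ExpressionMatrix":
    """Read a genes x tissues median-RPKM table.

    Genes with any missing tissue value are excluded (not imputed).
    """
    from .expression import ExpressionMatrix

    df = _read_tsv_matrix(path, "expression")
    df = df.dropna(axis=0, how="any").astype(float)
    return ExpressionMatrix(df)


def read_guide_coefficients(path: str | Path) -> KnockdownMatrix:
    df = _read_tsv_matrix(path, "guide coefficient")
    if df.isna().any().any():
        raise FormatError(f"{path}: missing cell in guide coefficient table")
    return KnockdownMatrix(
        genes=[str(g) for g in df.index],
        guides=[str(g) for g in df.columns],
        coefficients=df.to_numpy(dtype=float),
    )


def read_pvalue_table(path: str | Path) -> PValueTable:
    df = _read_tsv_matrix(path, "p-value")
    if df.shape[1] != 1:
        raise FormatError(f"{path}: p-value table must have exactly one value column")
    col = df.iloc[:, 0]
    if col.isna().any():
        raise FormatError(f"{path}: missing p-value")
    bad = col[(col < 0) | (col > 1)]
    if len(bad):
        raise FormatError(f"{path}: p-value outside [0,1] for gene {bad.index[0]!r}")
    return PValueTable({str(g): float(p) for g, p in col.items()})


def read_tss_table(path: str | Path) -> pd.DataFrame:
    """Read a TSS table: columns gene_id, contig, tss (0-based bp), strand."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "contig": str, "strand": str})
    required = {"gene_id", "contig", "tss", "strand"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: TSS table needs columns {sorted(required)}")
    if not df["strand"].isin(["+", "-"]).all():
        raise FormatError(f"{path}: strand must be '+' or '-'")
    df["tss"] = df["tss"].astype(int)
    if (df["tss"] < 0).any():
        raise FormatError(f"{path}: negative TSS coordinate")
    return df


# ---------------------------------------------------------------------------
# sequence access
# ---------------------------------------------------------------------------

_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def get_sequence(genome, interval: GenomicInterval, strand: str = "+") -> str:
    """Fetch an interval's sequence (uppercase); '-' returns the reverse complement.

    ``genome`` is any contig-keyed mapping whose values support ``len`` and
    slicing — a plain ``dict`` of strings or a ``pyfaidx.Fasta``.
    """
    if strand not in ("+", "-"):
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    try:
        contig = genome[interval.contig]
    except KeyError as exc:
        raise LookupError(f"contig {interval.contig!r} not in genome") from exc
    if interval.end > len(contig):
        raise LookupError(
            f"interval {interval.contig}:[{interval.start},{interval.end}) exceeds "
            f"contig length {len(contig)}"
        )
    seq = str(contig[interval.start : interval.end]).upper()
    return reverse_complement(seq) if strand == "-" else seq


def to_zero_based(position_1based: int) -> int:
    """Convert a 1-based (VCF-style) coordinate to the internal 0-based system.

    This is deliberately the only place in the package where the off-by-one
    conversion occurs.
    """
    if position_1based < 1:
        raise ValueError(f"1-based position must be >= 1, got {position_1based}")
    return position_1based - 1


class PeakIndex:
    """Sorted per-contig interval index answering 1-bp overlap queries."""

    def __init__(self, peaks: Iterable[GenomicInterval]):
        self._by_contig: dict[str, tuple[list[int], list[GenomicInterval]]] = {}
        grouped: dict[str, list[GenomicInterval]] = {}
        for p in peaks:
            grouped.setdefault(p.contig, []).append(p)
        for contig, ivs in grouped.items():
            ivs.sort(key=lambda i: (i.start, i.end))
            self._by_contig[contig] = ([iv.start for iv in ivs], ivs)

    def first_overlap(self, interval: GenomicInterval) -> GenomicInterval | None:
        entry = self._by_contig.get(interval.contig)
        if entry is None:
            return None
        starts, ivs = entry
        # candidates: peaks starting before interval.end
        hi = bisect_left(starts, interval.end)
        for iv in ivs[:hi]:
            if iv.end > interval.start:
                return iv
        return None

    def overlaps(self, interval: GenomicInterval) -> bool:
        return self.first_overlap(interval) is not None
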