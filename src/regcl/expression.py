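"""Tissue-wide expression profiles and Bray-Curtis similarity.

A gene's tissue-wide expression profile is the vector of its median RPKM
across a tissue panel (53 tissues in GTEx v6p).  Similarity between profiles
``a`` and ``b`` is the Bray-Curtis similarity

    sim(a, b) = 1 - sum_i |a_i - b_i| / sum_i (a_i + b_i),

defined as 1 when both vectors are entirely zero.  On non-negative vectors it
is bounded in [0, 1], symmetric, equals 1 iff the vectors are identical, and
weights large coordinates more heavily than small ones — the properties that
make it suitable for raw (untransformed) RPKM profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionProfile",
    "ExpressionMatrix",
    "bray_curtis",
    "rank_similar",
    "intersect_targets_with_similar",
]


@dataclass
class ExpressionProfile:
    gene_id: str
    values: np.ndarray
    tissues: list[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or len(v) != len(self.tissues):
            raise ValueError("profile length must match tissue labels")
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise ValueError("profile values must be finite and non-negative")
        self.values = v


class ExpressionMatrix:
    """Genes x tissues matrix of non-negative median expression values."""

    def __init__(self, data: pd.DataFrame):
        if data.index.has_duplicates:
            raise ValueError("duplicate gene ids in expression matrix")
        values = data.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)) or np.any(values < 0):
            raise ValueError("expression values must be finite and non-negative")
        self.data = data.astype(float)

    @property
    def genes(self) -> list[str]:
        return [str(g) for g in self.data.index]

    @property
    def tissues(self) -> list[str]:
        return [str(t) for t in self.data.columns]

    def __contains__(self, gene: str) -> bool:
        return gene in self.data.index

    def profile(self, gene: str) -> ExpressionProfile:
        if gene not in self.data.index:
            raise LookupError(f"gene {gene!r} not in expression matrix")
        return ExpressionProfile(gene, self.data.loc[gene].to_numpy(), self.tissues)


def _as_vector(x) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(x, ExpressionProfile):
        return x.values, x.tissues
    v = np.asarray(x, dtype=float)
    if v.ndim != 1:
        raise ValueError("expected a 1-d vector")
    if not np.all(np.isfinite(v)) or np.any(v < 0):
        raise ValueError("profile values must be finite and non-negative")
    return v, None


def bray_curtis(a, b) -> float:
    """Bray-Curtis similarity between two non-negative profiles.

    Returns 1.0 when both profiles sum to zero (two never-expressed genes are
    treated as maximally similar).
    """
    va, ta = _as_vector(a)
    vb, tb = _as_vector(b)
    if ta is not None and tb is not None and ta != tb:
        raise ValueError("profiles are over different tissue panels")
    if len(va) != len(vb):
        raise ValueError(f"profile lengths differ: {len(va)} vs {len(vb)}")
    total = va.sum() + vb.sum()
    if total == 0.0:
        return 1.0
    return float(1.0 - np.abs(va - vb).sum() / total)


def rank_similar(m: ExpressionMatrix, query: str, k: int) -> list[tuple[str, float]]:
    """The ``k`` genes most similar to ``query``, descending similarity.

    The query itself is excluded; ties are broken by lexicographic gene id.
    """
    if query not in m:
        raise LookupError(f"gene {query!r} not in expression matrix")
    n = len(m.data)
    if not (0 <= k <= n - 1):
        raise ValueError(f"k must be in [0, {n - 1}], got {k}")
    if k == 0:
        return []
    X = m.data.to_numpy(dtype=float)
    q = m.data.loc[query].to_numpy(dtype=float)
    num = np.abs(X - q).sum(axis=1)
    den = X.sum(axis=1) + q.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        sims = np.where(den == 0.0, 1.0, 1.0 - num / np.where(den == 0.0, 1.0, den))
    genes = np.asarray(m.genes, dtype=object)
    keep = genes != query
    order = np.lexsort((genes[keep], -sims[keep]))
    return [(str(genes[keep][i]), float(sims[keep][i])) for i in order[:k]]


def intersect_targets_with_similar(
    targets, ranked: list[tuple[str, float]]
) -> list[tuple[str, int, float]]:
    """Targets found among a ranked similar-gene list, with their 1-based ranks."""
    targets = set(targets)
    return [
        (gene, rank, sim)
        for rank, (gene, sim) in enumerate(ranked, start=1)
        if gene in targets
    ]
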