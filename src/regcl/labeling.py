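"""Positive/negative gene sets from knockdown experiments.

CRISPR route (guide-coefficient matrices, coefficients = log10 fold change):
a gene is a positive target of the perturbed TF when (1) its per-guide fold
changes are consistently > 1 or consistently < 1, (2) the average fold change
exceeds ``epsilon`` (or falls below ``1/epsilon``) in the shared direction,
and (3) the 10 kb promoter upstream of any of its TSSs overlaps a merged
ChIP-seq peak of the TF.  Genes whose coefficients are all exactly zero are
negatives; everything else is unlabeled.  Raising ``epsilon`` can only shrink
the positive set.

Class balancing follows the published recipe: negatives are ranked by
Bray-Curtis similarity of their tissue-wide expression profile to the
positive with the largest average coefficient, and the least-similar
``|positives|`` negatives are kept.

siRNA route (p-value tables): positives have p <= alpha (0.01) and peak
overlap; genes with p > alpha are negatives; small-p genes without peak
support are unlabeled.  siRNA sets are not balanced by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .expression import ExpressionMatrix, bray_curtis
from .formats import GenomicInterval, KnockdownMatrix, PeakIndex, PValueTable, merge_intervals
from .scanning import Promoter

__all__ = [
    "LabelConfig",
    "LabeledSet",
    "merge_peaks",
    "crispr_labels",
    "balance_negatives",
    "sirna_labels",
]

EPSILON_GRID = (1.01, 1.05, 1.1)


@dataclass(frozen=True)
class LabelConfig:
    epsilon: float = 1.05
    alpha: float = 0.01
    promoter_length: int = 10_000

    def __post_init__(self) -> None:
        if self.epsilon <= 1.0:
            raise ValueError(f"epsilon must be > 1, got {self.epsilon}")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")


@dataclass
class LabeledSet:
    positives: list[str]
    negatives: list[str]
    provenance: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.positives) & set(self.negatives):
            raise ValueError("positives and negatives overlap")


def merge_peaks(peak_sets: Iterable[Iterable[GenomicInterval]]) -> list[GenomicInterval]:
    """Union of several peak sets, overlapping/book-ended intervals coalesced."""
    flat = [p for peaks in peak_sets for p in peaks]
    return merge_intervals(flat) if flat else []


def _promoter_list(promoters, gene: str) -> Sequence[Promoter]:
    try:
        entry = promoters[gene]
    except KeyError as exc:
        raise ValueError(f"gene {gene!r} has no promoter record") from exc
    return [entry] if isinstance(entry, Promoter) else list(entry)


def _peak_hit(index: PeakIndex, proms: Sequence[Promoter]) -> GenomicInterval | None:
    for p in proms:
        hit = index.first_overlap(p.interval)
        if hit is not None:
            return hit
    return None


def crispr_labels(
    k: KnockdownMatrix,
    cfg: LabelConfig,
    merged_peaks: Sequence[GenomicInterval],
    promoters: Mapping[str, Promoter | Sequence[Promoter]],
) -> LabeledSet:
    """Unbalanced labels from a guide-coefficient matrix (criteria above).

    The "average fold change" is the arithmetic mean of the per-guide
    ``10**coefficient`` values.  A zero coefficient among nonzero ones breaks
    the consistency criterion (it is neither > 1 nor < 1).
    """
    index = PeakIndex(merged_peaks)
    positives, negatives, prov = [], [], {}
    for gene, coeffs in zip(k.genes, k.coefficients):
        proms = _promoter_list(promoters, gene)
        if np.all(coeffs == 0.0):
            negatives.append(gene)
            prov[gene] = {"label": "negative", "rule": "all-zero coefficients",
                          "mean_coeff": 0.0}
            continue
        fc = np.power(10.0, coeffs)
        up, down = bool(np.all(coeffs > 0)), bool(np.all(coeffs < 0))
        if not (up or down):
            continue  # mixed signs: unlabeled
        mean_fc = float(fc.mean())
        if up and not (mean_fc > cfg.epsilon):
            continue
        if down and not (mean_fc < 1.0 / cfg.epsilon):
            continue
        hit = _peak_hit(index, proms)
        if hit is None:
            continue  # differentially expressed but no binding evidence
        positives.append(gene)
        prov[gene] = {
            "label": "positive",
            "direction": "up" if up else "down",
            "mean_fold_change": mean_fc,
            "mean_coeff": float(coeffs.mean()),
            "epsilon": cfg.epsilon,
            "peak": (hit.contig, hit.start, hit.end),
        }
    return LabeledSet(positives, negatives, prov)


def balance_negatives(ls: LabeledSet, expr: ExpressionMatrix) -> LabeledSet:
    """Keep the ``|positives|`` negatives least similar to the reference positive.

    The reference is the positive with the largest average guide coefficient;
    similarity is Bray-Curtis on tissue-wide expression profiles; ties are
    broken by lexicographic gene id, so the result is input-order invariant.
    """
    if not ls.positives:
        raise ValueError("no positives to balance against")
    if len(ls.negatives) < len(ls.positives):
        raise ValueError(
            f"cannot balance: {len(ls.negatives)} negatives < "
            f"{len(ls.positives)} positives"
        )
    ref = max(
        sorted(ls.positives),
        key=lambda g: ls.provenance.get(g, {}).get("mean_coeff", 0.0),
    )
    if ref not in expr:
        raise LookupError(f"reference positive {ref!r} not in expression matrix")
    ref_profile = expr.profile(ref)
    scored = []
    for g in ls.negatives:
        if g not in expr:
            raise LookupError(f"negative {g!r} not in expression matrix")
        scored.append((bray_curtis(expr.profile(g), ref_profile), g))
    scored.sort()  # ascending similarity, lexicographic gene on ties
    kept = [g for _, g in scored[: len(ls.positives)]]
    prov = dict(ls.provenance)
    for sim, g in scored[: len(ls.positives)]:
        prov[g] = {**prov.get(g, {}), "balance_similarity": sim, "balance_ref": ref}
    return LabeledSet(list(ls.positives), kept, prov)


def sirna_labels(
    p: PValueTable,
    merged_peaks: Sequence[GenomicInterval],
    promoters: Mapping[str, Promoter | Sequence[Promoter]],
    cfg: LabelConfig = LabelConfig(),
) -> LabeledSet:
    """Labels from siRNA knockdown p-values (see module docstring)."""
    index = PeakIndex(merged_peaks)
    positives, negatives, prov = [], [], {}
    for gene, pval in p.pvalues.items():
        if pval > cfg.alpha:
            negatives.append(gene)
            prov[gene] = {"label": "negative", "p": pval}
            continue
        proms = _promoter_list(promoters, gene)
        hit = _peak_hit(index, proms)
        if hit is None:
            continue  # significant but unbound: unlabeled
        positives.append(gene)
        prov[gene] = {"label": "positive", "p": pval,
                      "peak": (hit.contig, hit.start, hit.end)}
    return LabeledSet(positives, negatives, prov)
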