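"""In-silico promoter mutagenesis: re-score, re-cluster, re-predict.

Single-nucleotide variants (1-based, VCF-style coordinates) are applied to a
promoter; the pipeline is then re-run — scan, IDBC clustering, featurization
under the training ``M_max``, classifier prediction — and the report pairs
wild-type and variant binding sites (with their R_i change), assigns every
wild-type cluster a fate (*retained* when some variant cluster passing the
information threshold overlaps its span, else *abolished*), lists newly
gained clusters, and gives the classifier output before and after.

Only SNVs are supported; indels are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .clustering import Cluster, IDBCParams, idbc
from .featurization import assemble_matrix, featurize_gene
from .formats import FormatError, reverse_complement, to_zero_based
from .modeling import TrainedModel
from .scanning import BASES, BindingSite, Promoter, iPWM, scan

__all__ = [
    "VariantSpec",
    "SiteChange",
    "MutationReport",
    "read_variants",
    "apply_variants",
    "MutatedGenome",
    "site_delta",
    "reevaluate_promoter",
    "knockout_variant",
    "design_cluster_knockouts",
]


@dataclass(frozen=True)
class VariantSpec:
    """A single-nucleotide variant; ``position`` is 1-based (VCF-like)."""

    id: str
    contig: str
    position: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError(f"{self.id}: only single-nucleotide variants supported")
        if self.ref.upper() not in BASES or self.alt.upper() not in BASES:
            raise ValueError(f"{self.id}: ref/alt must be A, C, G or T")
        if self.ref.upper() == self.alt.upper():
            raise ValueError(f"{self.id}: ref and alt are identical")
        if self.position < 1:
            raise ValueError(f"{self.id}: 1-based position must be >= 1")

    @property
    def pos0(self) -> int:
        return to_zero_based(self.position)


def read_variants(path: str | Path) -> list[VariantSpec]:
    """Read a variant TSV with columns id, contig, position (1-based), ref, alt."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"id", "contig", "position", "ref", "alt"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: variant table needs columns {sorted(required)}")
    out = []
    for _, row in df.iterrows():
        try:
            out.append(
                VariantSpec(row["id"], row["contig"], int(row["position"]),
                            row["ref"], row["alt"])
            )
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    return out


def apply_variants(sequence: str, offset: int, variants: Sequence[VariantSpec]) -> str:
    """Apply SNVs to a sequence whose first base sits at 0-based ``offset``.

    The stated ref base must match the sequence (guards against assembly or
    coordinate errors); length is preserved.
    """
    chars = list(sequence)
    for v in variants:
        i = v.pos0 - offset
        if not (0 <= i < len(chars)):
            raise ValueError(f"{v.id}: position {v.position} outside the sequence")
        if chars[i].upper() != v.ref.upper():
            raise ValueError(
                f"{v.id}: ref mismatch at {v.contig}:{v.position}: "
                f"sequence has {chars[i]!r}, variant states {v.ref!r}"
            )
        chars[i] = v.alt.upper()
    return "".join(chars)


class _PatchedContig:
    def __init__(self, base, edits: dict[int, str]):
        self._base = base
        self._edits = edits

    def __len__(self) -> int:
        return len(self._base)

    def __getitem__(self, key):
        if isinstance(key, slice):
            start, stop, step = key.indices(len(self._base))
            seq = list(str(self._base[key]))
            if step == 1:
                for pos, alt in self._edits.items():
                    if start <= pos < stop:
                        seq[pos - start] = alt
            return "".join(seq)
        pos = int(key)
        return self._edits.get(pos, str(self._base[pos : pos + 1]))


class MutatedGenome:
    """A genome view with SNVs applied lazily; ref bases verified eagerly."""

    def __init__(self, genome, variants: Sequence[VariantSpec]):
        self._genome = genome
        self._edits: dict[str, dict[int, str]] = {}
        for v in variants:
            contig = genome[v.contig]
            if v.pos0 >= len(contig):
                raise ValueError(f"{v.id}: position {v.position} beyond contig end")
            actual = str(contig[v.pos0 : v.pos0 + 1]).upper()
            if actual != v.ref.upper():
                raise ValueError(
                    f"{v.id}: ref mismatch at {v.contig}:{v.position}: "
                    f"genome has {actual!r}, variant states {v.ref!r}"
                )
            self._edits.setdefault(v.contig, {})[v.pos0] = v.alt.upper()

    def __getitem__(self, contig: str):
        base = self._genome[contig]
        edits = self._edits.get(contig)
        return _PatchedContig(base, edits) if edits else base


@dataclass
class SiteChange:
    """One wild/variant site pairing: retained (with delta), lost, or gained."""

    status: str  # "retained" | "lost" | "gained"
    wild: BindingSite | None = None
    variant: BindingSite | None = None

    @property
    def delta_ri(self) -> float | None:
        if self.wild is not None and self.variant is not None:
            return self.variant.r_i - self.wild.r_i
        return None


def site_delta(
    wild: Sequence[BindingSite], variant: Sequence[BindingSite]
) -> list[SiteChange]:
    """Pair sites by (tf, strand, span overlap); report lost/gained leftovers.

    A mutation may shift the best-scoring window, so pairing is by overlap
    (largest overlap wins), not exact coordinates.
    """
    remaining = list(variant)
    changes: list[SiteChange] = []
    for w in wild:
        best, best_ov = None, 0
        for v in remaining:
            if v.tf != w.tf or v.strand != w.strand or v.contig != w.contig:
                continue
            ov = min(w.end, v.end) - max(w.start, v.start)
            if ov > best_ov:
                best, best_ov = v, ov
        if best is None:
            changes.append(SiteChange("lost", wild=w))
        else:
            remaining.remove(best)
            changes.append(SiteChange("retained", wild=w, variant=best))
    changes.extend(SiteChange("gained", variant=v) for v in remaining)
    return changes


@dataclass
class MutationReport:
    site_changes: list[SiteChange]
    cluster_fates: list[tuple[Cluster, str]]  # fate: "retained" | "abolished"
    gained_clusters: list[Cluster]
    wild_clusters: list[Cluster]
    variant_clusters: list[Cluster]
    prediction_wild: int | None = None
    prediction_variant: int | None = None
    score_wild: float | None = None
    score_variant: float | None = None


def reevaluate_promoter(
    promoter: Promoter,
    variants: Sequence[VariantSpec],
    ipwms: Sequence[iPWM],
    params: IDBCParams,
    genome,
    model: TrainedModel | None = None,
    threshold_frac: float = 0.1,
) -> MutationReport:
    """Mutate -> scan -> cluster -> featurize -> predict, reporting changes.

    With an empty variant list the report is the wild-type identity: all
    clusters retained, every site delta zero, prediction unchanged.
    """
    def _pipeline(g):
        sites: list[BindingSite] = []
        for m in ipwms:
            sites.extend(scan(m, promoter, g, threshold_frac=threshold_frac))
        sites.sort(key=lambda s: (s.start, s.strand))
        return sites, idbc(sites, params)

    wild_sites, wild_clusters = _pipeline(genome)
    mgenome = MutatedGenome(genome, variants) if variants else genome
    var_sites, var_clusters = _pipeline(mgenome)

    fates = []
    for wc in wild_clusters:
        retained = any(wc.span.overlaps(vc.span) for vc in var_clusters)
        fates.append((wc, "retained" if retained else "abolished"))
    gained = [
        vc for vc in var_clusters
        if not any(vc.span.overlaps(wc.span) for wc in wild_clusters)
    ]

    report = MutationReport(
        site_changes=site_delta(wild_sites, var_sites),
        cluster_fates=fates,
        gained_clusters=gained,
        wild_clusters=wild_clusters,
        variant_clusters=var_clusters,
    )
    if model is not None:
        if model.m_max is None or model.mode is None or model.panel is None:
            raise ValueError("model lacks featurization schema (train on a FeatureMatrix)")
        for attr_pred, attr_score, clusters in (
            ("prediction_wild", "score_wild", wild_clusters),
            ("prediction_variant", "score_variant", var_clusters),
        ):
            feats = featurize_gene(clusters, promoter.tss, model.panel,
                                   mode=model.mode, strand=promoter.strand)
            fm = assemble_matrix({promoter.gene_id: feats}, model.panel,
                                 mode=model.mode, m_max=model.m_max)
            setattr(report, attr_pred, int(model.predict(fm)[0]))
            setattr(report, attr_score, float(model.predict_score(fm)[0]))
    return report


def design_cluster_knockouts(
    cluster: Cluster,
    ipwms: Sequence[iPWM],
    promoter: Promoter,
    params: IDBCParams,
    genome,
    threshold_frac: float = 0.1,
    base_variants: Sequence[VariantSpec] = (),
    max_knockouts: int = 8,
    id_prefix: str = "ko",
) -> list[VariantSpec]:
    """SNVs that abolish one wild-type cluster.

    Mutations are introduced sequentially into the strongest remaining binding
    site of whatever variant cluster still overlaps the wild span, re-scanning
    after each, until no overlapping cluster passes the information threshold.
    A single substitution usually suffices; overlapping windows that keep the
    cluster alive trigger further rounds.
    """
    by_tf = {m.tf: m for m in ipwms}
    variants = list(base_variants)
    own: list[VariantSpec] = []
    for k in range(max_knockouts):
        g = MutatedGenome(genome, variants) if variants else genome
        sites: list[BindingSite] = []
        for m in ipwms:
            sites.extend(scan(m, promoter, g, threshold_frac=threshold_frac))
        clusters = idbc(sites, params)
        live = [c for c in clusters if c.span.overlaps(cluster.span)]
        if not live:
            return own
        candidates = sorted((s for c in live for s in c.sites),
                            key=lambda s: -s.r_i)
        used = {v.pos0 for v in variants}
        chosen = None
        for s in candidates:
            cand = knockout_variant(by_tf[s.tf], s, id=f"{id_prefix}{k}")
            if cand.pos0 not in used:
                chosen = cand
                break
        if chosen is None:
            break
        variants.append(chosen)
        own.append(chosen)
    raise RuntimeError(
        f"cluster at {cluster.span.contig}:[{cluster.span.start},"
        f"{cluster.span.end}) not abolished within {max_knockouts} knockouts"
    )


def knockout_variant(m: iPWM, site: BindingSite, id: str = "ko") -> VariantSpec:
    """The SNV that most reduces a site's R_i.

    Picks the motif position/base substitution with the largest weight drop
    and maps it back through the site's strand to genomic coordinates.
    """
    code = [BASES.index(b) for b in site.sequence]
    drops = np.array([m.weights[j, code[j]] - m.weights[j].min() for j in range(m.width)])
    j = int(np.argmax(drops))
    alt_code = int(np.argmin(m.weights[j]))
    if alt_code == code[j]:
        raise ValueError("site already minimal; no knockout substitution exists")
    motif_ref, motif_alt = BASES[code[j]], BASES[alt_code]
    if site.strand == "+":
        pos0 = site.start + j
        ref, alt = motif_ref, motif_alt
    else:
        pos0 = site.start + (m.width - 1 - j)
        ref, alt = reverse_complement(motif_ref), reverse_complement(motif_alt)
    return VariantSpec(id=id, contig=site.contig, position=pos0 + 1, ref=ref, alt=alt)
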