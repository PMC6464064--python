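"""Fixed-length ML feature vectors from a gene's TFBS clusters.

Seven features describe each cluster: (1) distance to the TSS, (2) cluster
length, (3) total information content (sum of member R_i), and per TF in the
panel (4) the number of sites, (5) the number of strong sites
(R_i > R_sequence, strict), (6) the summed R_i of sites and (7) the summed
R_i of strong sites.  In homotypic mode (a single-TF panel) feature 6 is
identical to feature 3 and is dropped, leaving a 6-value block.

Genes differ in cluster count, so rows are aligned to a common slot count
``M_max`` by padding all-zero "null cluster" blocks at the distal (5') end of
the promoter; clusters are ordered 5'->3' along the promoter strand, placing
the most TSS-proximal cluster in the last slot.  Prediction-time featurization
reuses the training ``M_max``, truncating the most distal clusters if a gene
exceeds it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .clustering import Cluster

__all__ = [
    "ClusterFeatures",
    "FeatureMatrix",
    "featurize_gene",
    "assemble_matrix",
    "block_schema",
]

Panel = Sequence[tuple[str, float]]  # ordered (tf, R_sequence)


@dataclass
class ClusterFeatures:
    """Feature block of one cluster over a TF panel (arrays in panel order)."""

    distance_to_tss: float
    length: float
    info_content: float
    n_sites: np.ndarray
    n_strong: np.ndarray
    sum_ri: np.ndarray
    sum_strong_ri: np.ndarray

    def to_vector(self, mode: str) -> np.ndarray:
        head = [self.distance_to_tss, self.length, self.info_content]
        if mode == "heterotypic":
            per_tf = np.stack(
                [self.n_sites, self.n_strong, self.sum_ri, self.sum_strong_ri], axis=1
            ).ravel()
        elif mode == "homotypic":
            per_tf = np.stack([self.n_sites, self.n_strong, self.sum_strong_ri], axis=1).ravel()
        else:
            raise ValueError(f"unknown mode {mode!r}")
        return np.concatenate([head, per_tf])


def block_schema(panel: Panel, mode: str) -> list[tuple[str, str | None]]:
    """Column layout of one cluster block: (feature name, tf or None)."""
    cols: list[tuple[str, str | None]] = [
        ("distance_to_tss", None),
        ("length", None),
        ("info_content", None),
    ]
    per_tf = (
        ("n_sites", "n_strong", "sum_ri", "sum_strong_ri")
        if mode == "heterotypic"
        else ("n_sites", "n_strong", "sum_strong_ri")
    )
    for tf, _ in panel:
        cols.extend((name, tf) for name in per_tf)
    return cols


def featurize_gene(
    clusters: Sequence[Cluster],
    tss: int,
    panel: Panel,
    mode: str = "heterotypic",
    strand: str = "+",
) -> list[ClusterFeatures]:
    """Per-cluster feature blocks, ordered 5'->3' along the promoter strand."""
    if mode not in ("heterotypic", "homotypic"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "homotypic" and len(panel) != 1:
        raise ValueError("homotypic mode requires a single-TF panel")
    tf_index = {tf: i for i, (tf, _) in enumerate(panel)}
    r_seq = {tf: rs for tf, rs in panel}
    K = len(panel)
    ordered = sorted(clusters, key=lambda c: c.span.start, reverse=(strand == "-"))
    out = []
    for c in ordered:
        n_sites = np.zeros(K)
        n_strong = np.zeros(K)
        sum_ri = np.zeros(K)
        sum_strong = np.zeros(K)
        for s in c.sites:
            if s.tf not in tf_index:
                raise ValueError(f"site TF {s.tf!r} not in panel")
            i = tf_index[s.tf]
            n_sites[i] += 1
            sum_ri[i] += s.r_i
            if s.r_i > r_seq[s.tf]:  # strict: R_i == R_sequence is not "strong"
                n_strong[i] += 1
                sum_strong[i] += s.r_i
        out.append(
            ClusterFeatures(
                distance_to_tss=float(c.distance_to_tss(tss)),
                length=float(c.length),
                info_content=c.info_content,
                n_sites=n_sites,
                n_strong=n_strong,
                sum_ri=sum_ri,
                sum_strong_ri=sum_strong,
            )
        )
    return out


@dataclass
class FeatureMatrix:
    """Genes x (M_max x block) feature matrix with its column schema.

    ``schema[c]`` maps column ``c`` to ``(slot, feature name, tf-or-None)``;
    slot 0 is the most distal (5') cluster slot.
    """

    X: np.ndarray
    genes: list[str]
    schema: list[tuple[int, str, str | None]]
    m_max: int
    mode: str
    panel: list[tuple[str, float]]

    def column_of(self, slot: int, feature: str, tf: str | None = None) -> int:
        return self.schema.index((slot, feature, tf))


def assemble_matrix(
    features_by_gene: Mapping[str, Sequence[ClusterFeatures]],
    panel: Panel,
    mode: str = "heterotypic",
    m_max: int | None = None,
) -> FeatureMatrix:
    """Stack per-gene blocks into a fixed-width matrix with 5' null padding.

    ``m_max`` defaults to the dataset maximum (floor 1).  Genes with fewer
    clusters get all-zero blocks in the distal slots; genes with more (only
    possible when reusing a training ``m_max`` at prediction time) keep their
    ``m_max`` most TSS-proximal clusters.
    """
    block = block_schema(panel, mode)
    B = len(block)
    genes = list(features_by_gene)
    if m_max is None:
        m_max = max((len(v) for v in features_by_gene.values()), default=0)
        m_max = max(m_max, 1)
    if m_max < 1:
        raise ValueError("m_max must be >= 1")
    X = np.zeros((len(genes), m_max * B))
    for r, gene in enumerate(genes):
        feats = list(features_by_gene[gene])
        if feats and len({len(f.n_sites) for f in feats}) != 1:
            raise ValueError(f"gene {gene}: inconsistent block sizes")
        feats = feats[-m_max:]  # keep the TSS-proximal (3'-most) clusters
        offset = m_max - len(feats)  # null clusters pad the 5' end
        for j, f in enumerate(feats):
            v = f.to_vector(mode)
            if len(v) != B:
                raise ValueError(f"gene {gene}: block size {len(v)} != schema {B}")
            X[r, (offset + j) * B : (offset + j + 1) * B] = v
    schema = [(slot, name, tf) for slot in range(m_max) for name, tf in block]
    return FeatureMatrix(X=X, genes=genes, schema=schema, m_max=m_max,
                         mode=mode, panel=list(panel))
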