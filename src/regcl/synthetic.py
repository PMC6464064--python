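"""Seeded generators for every input the pipeline consumes.

The generators emulate the study conditions end to end: random iPWMs of a
requested information content, promoters with planted binding-site clusters
inside DNase-accessible intervals, ChIP-seq-like peaks over the plants,
block-structured tissue-wide expression matrices, and knockdown matrices
with planted consistent-sign targets.  A truth table records every plant so
each stage — and the full classifier pipeline — can be tested without any
external download.

Design of the planted signal
----------------------------
Positive genes carry 1..``clusters_per_positive`` homotypic clusters.  Each
cluster's total-information target is ``I * (1 + 5*(epsilon - 1))`` with
multiplicative LogNormal(0, ``cluster_info_sigma``) noise, where ``I`` is the
clustering threshold (the TF's R_sequence) and ``epsilon`` the planted
knockdown fold-change threshold.  Weak perturbations (epsilon = 1.01) thus
plant clusters that sit marginally at the threshold, strong ones
(epsilon = 1.1) clear it comfortably — reproducing the observed coupling
between differential-expression strength and cluster-feature separability.
The default sizes (200 genes, 100 positives, 53 tissues, 10 kb promoters,
d = 25) are the study conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .clustering import IDBCParams, idbc
from .expression import ExpressionMatrix
from .featurization import assemble_matrix, featurize_gene, FeatureMatrix
from .formats import GenomicInterval, iPWMFile, KnockdownMatrix, merge_intervals
from .labeling import LabelConfig, balance_negatives, crispr_labels, merge_peaks
from .modeling import EvalReport, TrainedModel, cross_validate, roc_auc, train
from .scanning import BASES, Promoter, iPWM, make_promoter, restrict_to_accessible, scan, score_site
from .formats import reverse_complement

__all__ = [
    "SimConfig",
    "SimulatedPromoters",
    "BenchmarkResult",
    "gen_ipwm",
    "design_site",
    "gen_promoters",
    "gen_expression",
    "gen_knockdown",
    "run_planted_benchmark",
]


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for the synthetic generators."""

    n_genes: int = 200
    n_positives: int = 100
    n_tissues: int = 53
    promoter_length: int = 10_000
    ipwm_width: int = 12
    ipwm_info: float = 15.0        # bits; a sharp primary motif — calibrated so
                                   # background alone forms a passing cluster in
                                   # < 5% of negative promoters
    clusters_per_positive: int = 2  # per-gene count drawn uniformly from 1..this
    vary_cluster_count: bool = True
    sites_per_cluster: int = 3
    epsilon: float = 1.1
    n_guides: int = 4
    decoy_fraction: float = 0.0    # non-targets given mixed-sign coefficients
    cluster_radius: int = 25       # IDBC d
    cluster_info_sigma: float = 0.25
    site_fractions: tuple[float, ...] | None = None  # explicit per-site R_i/R_seq
    site_fraction_floor: float = 0.15  # keep planted sites above the 0.1 scan cut
    gc: float = 0.5
    n_background_dhs: int = 3
    dhs_length: int = 300
    dhs_pad: tuple[int, int] = (20, 80)
    peak_pad: int = 50
    threshold_frac: float = 0.1

    def __post_init__(self) -> None:
        if not (0 < self.n_positives <= self.n_genes):
            raise ValueError("need 0 < n_positives <= n_genes")
        if self.sites_per_cluster < 1 or self.clusters_per_positive < 1:
            raise ValueError("plant counts must be positive")
        if self.epsilon <= 1.0:
            raise ValueError("epsilon must be > 1")
        if not (0.0 < self.gc < 1.0):
            raise ValueError("gc must be in (0,1)")
        if self.site_fractions is not None and any(
            not (0.0 < f <= 2.0) for f in self.site_fractions
        ):
            raise ValueError("site strength fractions must be in (0, 2]")

    @property
    def cluster_info_factor(self) -> float:
        """Mean planted cluster information as a multiple of the threshold I."""
        return 1.0 + 5.0 * (self.epsilon - 1.0)


# ---------------------------------------------------------------------------
# iPWM generation
# ---------------------------------------------------------------------------

def _column_info(f: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(f > 0, f * np.log2(np.where(f > 0, f, 1.0)), 0.0)
    return float(np.sum(2.0 + plogp.sum(axis=1)))


def gen_ipwm(
    width: int,
    target_info: float,
    seed,
    tf: str = "TF1",
    cell_line: str = "sim",
    tolerance: float = 0.5,
    floor: float = -10.0,
) -> iPWMFile:
    """A random iPWM whose information content is ``target_info`` +/- ``tolerance``.

    Per-position base frequencies are drawn from a Dirichlet and sharpened by
    a temperature chosen by bisection (temperature 0 = uniform = 0 bits;
    temperature -> inf = one-hot = 2 bits/position), so the realized content
    converges monotonically onto the target.  Weights are ``2 + log2 f`` with
    a floor at ``floor`` bits for vanishing frequencies; the realized content
    is stored as R_sequence metadata.  Deterministic under the seed.
    """
    if not (0.0 < target_info <= 2.0 * width):
        raise ValueError(
            f"target information {target_info} infeasible for width {width} "
            f"(max {2.0 * width} bits)"
        )
    rng = np.random.default_rng(seed)
    logf0 = np.log(np.clip(rng.dirichlet(np.full(4, 0.5), size=width), 1e-12, None))

    def freqs(t: float) -> np.ndarray:
        z = t * logf0
        z -= z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    lo, hi = 0.0, 1.0
    while _column_info(freqs(hi)) < target_info and hi < 1e6:
        hi *= 2.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if _column_info(freqs(mid)) < target_info:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-9:
            break
    f = freqs(0.5 * (lo + hi))
    realized = _column_info(f)
    if abs(realized - target_info) > tolerance:
        raise ValueError(
            f"could not reach information target {target_info} at width {width} "
            f"(achieved {realized:.3f})"
        )
    with np.errstate(divide="ignore"):
        weights = np.maximum(2.0 + np.log2(np.where(f > 0, f, 1e-300)), floor)
    return iPWMFile(tf=tf, cell_line=cell_line, weights=weights,
                    r_sequence_meta=realized)


def design_site(m: iPWM, target_ri: float, rng: np.random.Generator) -> str:
    """A k-mer whose R_i approximates ``target_ri`` from above.

    Starts from the consensus and greedily applies, in random position order,
    the largest single-base weight reduction that does not overshoot below
    the target; the realized score therefore satisfies
    ``target_ri <= R_i <= max score`` whenever the target is attainable.
    """
    W = m.weights
    cons = list(np.argmax(W, axis=1))
    score = float(W[np.arange(m.width), cons].sum())
    need = score - target_ri
    for j in rng.permutation(m.width):
        if need <= 0:
            break
        cuts = W[j, cons[j]] - W[j]  # reduction per candidate base
        cuts = [(c, b) for b, c in enumerate(cuts) if 0 < c <= need]
        if cuts:
            c, b = max(cuts)
            cons[j] = b
            need -= c
    return "".join(BASES[b] for b in cons)


# ---------------------------------------------------------------------------
# promoters with planted clusters
# ---------------------------------------------------------------------------

@dataclass
class SimulatedPromoters:
    """Generated promoter landscape plus the planted truth."""

    genome: dict[str, str]
    tss: pd.DataFrame
    promoters: dict[str, Promoter]          # accessibility-masked
    dhs: list[GenomicInterval]
    peaks: list[GenomicInterval]
    positives: list[str]
    negatives: list[str]
    truth_sites: pd.DataFrame
    truth_clusters: pd.DataFrame


def _random_sequence(rng: np.random.Generator, n: int, gc: float) -> list[str]:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return [BASES[i] for i in rng.choice(4, size=n, p=p)]


def gen_promoters(
    cfg: SimConfig, ipwms: Sequence[iPWM], rng: np.random.Generator
) -> SimulatedPromoters:
    """Promoter FASTA-equivalent, TSS table, DHS/peak intervals and truth.

    One contig per gene; the TSS sits at the contig end so the promoter is
    the whole contig ('+' strand).  Positive genes receive homotypic planted
    clusters (the cluster's TF drawn from the panel): consensus-derived site
    instances spaced within twice the seed radius so they merge into one IDBC
    group, with summed planted R_i targeting the threshold multiple described
    in the module docstring.  DHS intervals cover every plant, plus random
    background accessibility in all genes; peaks cover plants only.
    """
    L = cfg.promoter_length
    d = cfg.cluster_radius
    genes = [f"G{i:05d}" for i in range(cfg.n_genes)]
    positives = sorted(
        rng.choice(cfg.n_genes, size=cfg.n_positives, replace=False).tolist()
    )
    pos_set = {genes[i] for i in positives}

    genome: dict[str, str] = {}
    dhs: list[GenomicInterval] = []
    peaks: list[GenomicInterval] = []
    site_rows, cluster_rows = [], []
    promoters: dict[str, Promoter] = {}
    tss_rows = []

    for gene in genes:
        seq = _random_sequence(rng, L, cfg.gc)
        gene_dhs: list[GenomicInterval] = []
        if gene in pos_set:
            n_clusters = (
                int(rng.integers(1, cfg.clusters_per_positive + 1))
                if cfg.vary_cluster_count
                else cfg.clusters_per_positive
            )
            seg = L // n_clusters
            for ci in range(n_clusters):
                m = ipwms[int(rng.integers(len(ipwms)))]
                r_seq = m.r_sequence
                span_len_max = cfg.sites_per_cluster * (m.width + 2 * d)
                lo = ci * seg + 100
                hi = (ci + 1) * seg - span_len_max - 100
                if hi <= lo:
                    raise ValueError("plant does not fit promoter segment")
                start = int(rng.integers(lo, hi))
                if cfg.site_fractions is not None:
                    targets = [f * r_seq for f in cfg.site_fractions]
                else:
                    total = (
                        r_seq
                        * cfg.cluster_info_factor
                        * float(np.exp(rng.normal(0.0, cfg.cluster_info_sigma)))
                    )
                    split = rng.dirichlet(np.full(cfg.sites_per_cluster, 5.0))
                    targets = np.clip(
                        total * split, cfg.site_fraction_floor * r_seq, 1.9 * r_seq
                    ).tolist()
                x = start
                planted = []
                for si, t in enumerate(targets):
                    kmer = design_site(m, t, rng)
                    strand = "+" if rng.random() < 0.5 else "-"
                    inserted = kmer if strand == "+" else reverse_complement(kmer)
                    seq[x : x + m.width] = list(inserted)
                    realized = score_site(m, kmer)
                    planted.append((x, strand, kmer, t, realized))
                    site_rows.append(
                        {"gene": gene, "tf": m.tf, "cluster_index": ci, "start": x,
                         "strand": strand, "sequence": kmer, "target_ri": t,
                         "realized_ri": realized}
                    )
                    if si < len(targets) - 1:
                        gap = int(rng.integers(2, 2 * d - m.width))
                        x += m.width + gap
                span_end = planted[-1][0] + m.width
                cluster_rows.append(
                    {"gene": gene, "tf": m.tf, "cluster_index": ci, "start": start,
                     "end": span_end,
                     "total_target_ri": float(sum(t for *_, t, _ in planted)),
                     "total_realized_ri": float(sum(r for *_, r in planted))}
                )
                pad_l = int(rng.integers(*cfg.dhs_pad))
                pad_r = int(rng.integers(*cfg.dhs_pad))
                gene_dhs.append(
                    GenomicInterval(gene, max(0, start - pad_l), min(L, span_end + pad_r))
                )
                peaks.append(
                    GenomicInterval(
                        gene, max(0, start - cfg.peak_pad), min(L, span_end + cfg.peak_pad)
                    )
                )
        for _ in range(cfg.n_background_dhs):
            s = int(rng.integers(0, max(1, L - cfg.dhs_length)))
            gene_dhs.append(GenomicInterval(gene, s, min(L, s + cfg.dhs_length)))
        gene_dhs = merge_intervals(gene_dhs)
        dhs.extend(gene_dhs)
        genome[gene] = "".join(seq)
        tss_rows.append({"gene_id": gene, "contig": gene, "tss": L, "strand": "+"})
        prom = make_promoter(gene, gene, tss=L, strand="+", contig_length=L, length=L)
        promoters[gene] = restrict_to_accessible(prom, gene_dhs)

    return SimulatedPromoters(
        genome=genome,
        tss=pd.DataFrame(tss_rows),
        promoters=promoters,
        dhs=dhs,
        peaks=peaks,
        positives=sorted(pos_set),
        negatives=[g for g in genes if g not in pos_set],
        truth_sites=pd.DataFrame(site_rows),
        truth_clusters=pd.DataFrame(cluster_rows),
    )


# ---------------------------------------------------------------------------
# expression and knockdown matrices
# ---------------------------------------------------------------------------

def gen_expression(
    n_tissues: int,
    groups: dict[str, Sequence[str]],
    rng: np.random.Generator,
    scale_sigma: float = 0.3,
    noise_sigma: float = 0.2,
) -> ExpressionMatrix:
    """Block-structured expression: one log-normal tissue archetype per group;
    members are the archetype times a gene scale factor times multiplicative
    noise, so within-group Bray-Curtis similarity exceeds between-group.
    """
    rows, index = [], []
    for name, members in groups.items():
        members = list(members)
        if not members:
            raise ValueError(f"group {name!r} is empty")
        archetype = rng.lognormal(mean=1.0, sigma=1.0, size=n_tissues)
        for gene in members:
            scale = float(np.exp(rng.normal(0.0, scale_sigma)))
            noise = np.exp(rng.normal(0.0, noise_sigma, size=n_tissues))
            rows.append(archetype * scale * noise)
            index.append(gene)
    tissues = [f"tissue_{i:02d}" for i in range(n_tissues)]
    return ExpressionMatrix(pd.DataFrame(rows, index=index, columns=tissues))


def gen_knockdown(
    genes: Sequence[str],
    targets: Sequence[str],
    n_guides: int,
    epsilon: float,
    rng: np.random.Generator,
    decoy_fraction: float = 0.0,
) -> KnockdownMatrix:
    """Guide-coefficient matrix with planted targets.

    Target rows get same-sign coefficients with every per-guide fold change
    beyond ``epsilon`` (or ``1/epsilon``), so the planted targets satisfy the
    consistency and threshold labeling criteria at that epsilon; non-targets
    are exact zeros; an optional fraction of non-targets become mixed-sign
    decoys that stay unlabeled.
    """
    if epsilon <= 1.0:
        raise ValueError("epsilon must be > 1")
    target_set = set(targets)
    non_targets = [g for g in genes if g not in target_set]
    n_decoys = int(round(decoy_fraction * len(non_targets)))
    decoys = set(
        np.array(non_targets, dtype=object)[
            rng.choice(len(non_targets), size=n_decoys, replace=False)
        ].tolist()
        if n_decoys
        else []
    )
    log_eps = np.log10(epsilon)
    coeffs = np.zeros((len(genes), n_guides))
    for i, g in enumerate(genes):
        if g in target_set:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            u = rng.uniform(0.2, 1.0, size=n_guides)
            coeffs[i] = sign * (1.0 + u) * log_eps
        elif g in decoys:
            c = rng.uniform(0.2, 1.0, size=n_guides) * log_eps
            c[0] *= -1.0  # guaranteed mixed signs
            coeffs[i] = c
    guides = [f"guide_{j}" for j in range(n_guides)]
    return KnockdownMatrix(genes=list(genes), guides=guides, coefficients=coeffs)


# ---------------------------------------------------------------------------
# end-to-end planted-target benchmark
# ---------------------------------------------------------------------------

@dataclass
class BenchmarkResult:
    cfg: SimConfig
    ipwm: iPWM
    sim: SimulatedPromoters
    labels: object
    features: FeatureMatrix
    y: np.ndarray
    report: EvalReport
    model: TrainedModel
    auc: float


def run_planted_benchmark(
    seed: int,
    cfg: SimConfig | None = None,
    rounds: int = 10,
    folds: int = 10,
    **overrides,
) -> BenchmarkResult:
    """The full homotypic pipeline on planted data, deterministic per seed.

    generate -> scan accessible promoters -> IDBC (I = R_sequence, d = 25) ->
    homotypic featurization -> CRISPR labeling at the planted epsilon ->
    similarity-based balancing -> decision tree, ``rounds`` x ``folds``
    stratified cross-validation.
    """
    cfg = replace(cfg or SimConfig(), **overrides) if overrides else (cfg or SimConfig())
    ss = np.random.SeedSequence(seed)
    s_ipwm, s_prom, s_expr, s_kd, s_cv = ss.spawn(5)
    ipwm = iPWM.from_file(gen_ipwm(cfg.ipwm_width, cfg.ipwm_info, seed=s_ipwm))
    r_seq = ipwm.r_sequence
    sim = gen_promoters(cfg, [ipwm], np.random.default_rng(s_prom))

    kd = gen_knockdown(
        list(sim.promoters), sim.positives, cfg.n_guides, cfg.epsilon,
        np.random.default_rng(s_kd), cfg.decoy_fraction,
    )
    label_cfg = LabelConfig(epsilon=cfg.epsilon, promoter_length=cfg.promoter_length)
    labels = crispr_labels(kd, label_cfg, merge_peaks([sim.peaks]), sim.promoters)
    expr = gen_expression(
        cfg.n_tissues,
        {"target": sim.positives, "background": sim.negatives},
        np.random.default_rng(s_expr),
    )
    labels = balance_negatives(labels, expr)

    params = IDBCParams(d=cfg.cluster_radius, I=r_seq)
    panel = [(ipwm.tf, r_seq)]
    feats = {}
    for gene in labels.positives + labels.negatives:
        prom = sim.promoters[gene]
        sites = scan(ipwm, prom, sim.genome, threshold_frac=cfg.threshold_frac)
        clusters = idbc(sites, params)
        feats[gene] = featurize_gene(clusters, prom.tss, panel, mode="homotypic",
                                     strand=prom.strand)
    fm = assemble_matrix(feats, panel, mode="homotypic")
    y = np.array([1] * len(labels.positives) + [0] * len(labels.negatives))

    cv_seed = int(s_cv.generate_state(1)[0] % (2**31 - 1))
    report = cross_validate(fm, y, rounds=rounds, folds=folds,
                            kind="decision_tree", seed=cv_seed)
    model = train(fm, y, kind="decision_tree", seed=cv_seed)
    _, auc_value = roc_auc(model, fm, y)
    return BenchmarkResult(cfg=cfg, ipwm=ipwm, sim=sim, labels=labels,
                           features=fm, y=y, report=report, model=model,
                           auc=auc_value)
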