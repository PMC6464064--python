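import numpy as np
import pytest

from regcl import (
    GenomicInterval,
    IDBCParams,
    MutatedGenome,
    VariantSpec,
    apply_variants,
    iPWM,
    knockout_variant,
    reevaluate_promoter,
    reverse_complement,
    scan,
    score_site,
    site_delta,
)
from regcl.scanning import BindingSite, Promoter


class TestVariantSpec:
    def test_validation(self):
        with pytest.raises(ValueError):
            VariantSpec("v", "c", 5, "A", "A")  # ref == alt
        with pytest.raises(ValueError):
            VariantSpec("v", "c", 5, "AT", "A")  # not an SNV
        with pytest.raises(ValueError):
            VariantSpec("v", "c", 0, "A", "C")  # 1-based
        v = VariantSpec("rs538610162", "chr19", 39540296, "C", "G")
        assert v.pos0 == 39540295


class TestApplyVariants:
    def test_first_base_substitution(self):
        # a G>C change at the site's first base: GAGGGGGCATC -> CAGGGGGCATC
        out = apply_variants("GAGGGGGCATC", 100, [VariantSpec("v", "c", 101, "G", "C")])
        assert out == "CAGGGGGCATC"

    def test_ref_mismatch_names_position(self):
        with pytest.raises(ValueError, match="c:101"):
            apply_variants("GAGG", 100, [VariantSpec("v", "c", 101, "A", "C")])

    def test_two_nonoverlapping_variants(self):
        out = apply_variants("AAAA", 0, [VariantSpec("v1", "c", 1, "A", "C"),
                                         VariantSpec("v2", "c", 4, "A", "G")])
        assert out == "CAAG"

    def test_outside_sequence_rejected(self):
        with pytest.raises(ValueError):
            apply_variants("AAAA", 0, [VariantSpec("v", "c", 9, "A", "C")])

    def test_batch_equals_sequential(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=60))
        positions = rng.choice(60, size=4, replace=False)
        variants = []
        for i, p in enumerate(positions):
            ref = seq[p]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            variants.append(VariantSpec(f"v{i}", "c", int(p) + 1, ref, alt))
        batch = apply_variants(seq, 0, variants)
        seq2 = seq
        for v in variants:
            seq2 = apply_variants(seq2, 0, [v])
        assert batch == seq2


class TestMutatedGenome:
    def test_slicing_applies_edits(self):
        g = MutatedGenome({"c": "ACGTACGT"}, [VariantSpec("v", "c", 3, "G", "T")])
        assert g["c"][0:8] == "ACTTACGT"
        assert g["c"][2] == "T"
        assert len(g["c"]) == 8

    def test_eager_ref_check(self):
        with pytest.raises(ValueError, match="ref mismatch"):
            MutatedGenome({"c": "ACGT"}, [VariantSpec("v", "c", 1, "G", "T")])

    def test_untouched_contig_passthrough(self):
        g = MutatedGenome({"a": "AAAA", "b": "CCCC"},
                          [VariantSpec("v", "a", 1, "A", "G")])
        assert str(g["b"][0:4]) == "CCCC"


def bsite(start, r_i, tf="T", strand="+", width=4):
    return BindingSite(tf=tf, contig="c", start=start, strand=strand,
                       sequence="A" * width, r_i=r_i)


class TestSiteDelta:
    def test_identity(self):
        sites = [bsite(10, 5.0), bsite(30, 2.0, strand="-")]
        changes = site_delta(sites, sites)
        assert all(c.status == "retained" and c.delta_ri == 0.0 for c in changes)

    def test_shifted_site_paired_by_overlap(self):
        changes = site_delta([bsite(10, 5.0)], [bsite(11, 3.5)])
        [c] = changes
        assert c.status == "retained"
        assert c.delta_ri == pytest.approx(-1.5)

    def test_lost_and_gained(self):
        changes = site_delta([bsite(10, 5.0)], [bsite(100, 4.0)])
        assert {c.status for c in changes} == {"lost", "gained"}

    def test_strand_and_tf_must_match(self):
        changes = site_delta([bsite(10, 5.0, strand="+")],
                             [bsite(10, 5.0, strand="-")])
        assert {c.status for c in changes} == {"lost", "gained"}


# hand fixture: consensus AAAC scores 8 bits, any mismatch drops it below the
# 0.1 * R_sequence = 0.8 scan threshold; two planted sites, I = 10 so neither
# site alone sustains the cluster.  The all-T background contains no G, so the
# minus strand (which would need a GTTT window) can never match.
FIX_W = np.full((4, 4), -6.0)
for _j, _b in enumerate("AAAC"):
    FIX_W[_j, "ACGT".index(_b)] = 2.0
FIX_M = iPWM(tf="FIX", weights=FIX_W, r_sequence_meta=8.0)
FIX_PARAMS = IDBCParams(d=25, I=10.0)


def fixture_genome():
    seq = list("T" * 100)
    seq[10:14] = "AAAC"
    seq[40:44] = "AAAC"
    return {"c": "".join(seq)}


def fixture_promoter():
    return Promoter("g", "c", 100, "+", GenomicInterval("c", 0, 100))


class TestReevaluatePromoter:
    def test_empty_variant_list_is_identity(self):
        report = reevaluate_promoter(fixture_promoter(), [], [FIX_M], FIX_PARAMS,
                                     fixture_genome())
        assert len(report.wild_clusters) == 1
        assert [f for _, f in report.cluster_fates] == ["retained"]
        assert all(c.status == "retained" and c.delta_ri == 0.0
                   for c in report.site_changes)
        assert report.gained_clusters == []

    def test_knocking_one_site_below_threshold_abolishes_cluster(self):
        # 16 bits from two 8-bit sites; losing one leaves 8 < I = 10
        v = VariantSpec("ko", "c", 11, "A", "T")
        report = reevaluate_promoter(fixture_promoter(), [v], [FIX_M], FIX_PARAMS,
                                     fixture_genome())
        assert [f for _, f in report.cluster_fates] == ["abolished"]
        assert sum(c.status == "lost" for c in report.site_changes) == 1
        assert report.variant_clusters == []

    def test_variant_outside_sites_and_seed_radius_changes_nothing(self, rng):
        wild = reevaluate_promoter(fixture_promoter(), [], [FIX_M], FIX_PARAMS,
                                   fixture_genome())
        for _ in range(10):
            pos = int(rng.choice([p for p in range(100)
                                  if not (10 - 29 <= p <= 43 + 29)]))
            genome = fixture_genome()
            ref = genome["c"][pos]
            # alt restricted so the substitution cannot complete a new motif
            # match on either strand (AAAC needs three adjacent As; GTTT a G)
            alt = str(rng.choice([b for b in "AC" if b != ref]))
            v = VariantSpec("far", "c", pos + 1, ref, alt)
            report = reevaluate_promoter(fixture_promoter(), [v], [FIX_M],
                                         FIX_PARAMS, fixture_genome())
            assert [f for _, f in report.cluster_fates] == ["retained"]
            assert [c.span for c in report.variant_clusters] == [
                c.span for c in wild.wild_clusters
            ]
            assert all(c.status == "retained" for c in report.site_changes)

    def test_batch_variants_equal_sequential_application(self):
        v1 = VariantSpec("v1", "c", 11, "A", "T")
        v2 = VariantSpec("v2", "c", 41, "A", "T")
        both = reevaluate_promoter(fixture_promoter(), [v1, v2], [FIX_M],
                                   FIX_PARAMS, fixture_genome())
        staged_genome = MutatedGenome(fixture_genome(), [v1])
        staged = reevaluate_promoter(fixture_promoter(), [v2], [FIX_M],
                                     FIX_PARAMS, staged_genome)
        assert [s.start for s in _variant_sites(both)] == [
            s.start for s in _variant_sites(staged)
        ]
        assert both.variant_clusters == staged.variant_clusters == []


def _variant_sites(report):
    return [c.variant for c in report.site_changes if c.variant is not None]


class TestDesignClusterKnockouts:
    def test_minimal_knockout_set_abolishes_cluster(self):
        from regcl import design_cluster_knockouts, idbc

        genome = fixture_genome()
        prom = fixture_promoter()
        [cluster] = idbc(scan(FIX_M, prom, genome), FIX_PARAMS)
        kos = design_cluster_knockouts(cluster, [FIX_M], prom, FIX_PARAMS, genome)
        assert len(kos) == 1  # 16 bits - 8-bit site leaves 8 < I = 10
        report = reevaluate_promoter(prom, kos, [FIX_M], FIX_PARAMS, genome)
        assert [f for _, f in report.cluster_fates] == ["abolished"]


class TestKnockoutVariant:
    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_reduces_site_score_on_both_strands(self, sim_ipwm, strand):
        kmer = sim_ipwm.consensus
        inserted = kmer if strand == "+" else reverse_complement(kmer)
        seq = "T" * 20 + inserted + "T" * 20
        genome = {"c": seq}
        prom = Promoter("g", "c", len(seq), "+", GenomicInterval("c", 0, len(seq)))
        wild = [s for s in scan(sim_ipwm, prom, genome) if s.start == 20
                and s.strand == strand]
        assert wild, "planted consensus site not recovered"
        v = knockout_variant(sim_ipwm, wild[0])
        mutated = MutatedGenome(genome, [v])
        after = [s for s in scan(sim_ipwm, prom, mutated, threshold_frac=-10)
                 if s.start == 20 and s.strand == strand]
        drop = sim_ipwm.max_score - (after[0].r_i if after else -np.inf)
        expected = float(np.max(sim_ipwm.weights.max(axis=1)
                                - sim_ipwm.weights.min(axis=1)))
        assert drop == pytest.approx(expected)
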