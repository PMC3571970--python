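"""Intergenic classification, promoter windows, bimodality assessment."""

import numpy as np
import pytest
from scipy import stats as sps

from endoreg import intergenic_analysis as ia
from endoreg.genome_model import TURecord
from conftest import make_genome


def two_gene_genome(strand_left, strand_right, circular=True):
    return make_genome(
        "ACGT" * 10,
        genes=[("gL", 0, 10, strand_left, "coding"),
               ("gR", 20, 30, strand_right, "coding")],
        circular=circular,
    )


class TestClassification:
    @pytest.mark.parametrize("sl,sr,expected", [
        ("+", "-", "convergent"),
        ("-", "+", "divergent"),
        ("+", "+", "tandem"),
        ("-", "-", "tandem"),
    ])
    def test_orientation_classes(self, sl, sr, expected):
        regions = ia.classify_intergenic(two_gene_genome(sl, sr, circular=False))
        assert len(regions) == 1
        r = regions[0]
        assert (r.start, r.end) == (10, 20)
        assert r.orientation_class == expected

    def test_circular_includes_origin_spanning_gap(self):
        regions = ia.classify_intergenic(two_gene_genome("+", "+"))
        assert len(regions) == 2
        wrap = [r for r in regions if r.start == 30][0]
        assert wrap.end == 0 or wrap.end < wrap.start or wrap.end == 0
        assert wrap.length(40) == 10

    def test_zero_gap_skipped_and_overlap_warns(self):
        genome = make_genome(
            "ACGT" * 10,
            genes=[("g1", 0, 10, "+", "coding"), ("g2", 10, 20, "+", "coding"),
                   ("g3", 18, 30, "+", "coding")],
            circular=False,
        )
        with pytest.warns(UserWarning, match="overlapping"):
            regions = ia.classify_intergenic(genome)
        assert regions == []

    def test_regions_partition_nongenic_sequence(self):
        genome = make_genome(
            "A" * 100,
            genes=[("g1", 5, 20, "+", "coding"), ("g2", 30, 50, "-", "coding"),
                   ("g3", 60, 90, "+", "coding")],
        )
        regions = ia.classify_intergenic(genome)
        total = sum(r.length(100) for r in regions) + sum(
            g.length for g in genome.genes
        )
        assert total == 100

    def test_class_counts_invariant_under_rotation(self):
        base = [("g1", 5, 20, "+"), ("g2", 30, 50, "-"), ("g3", 60, 90, "+")]
        counts = []
        for shift in (0, 37):
            genes = [(gid, (s + shift) % 100, ((e - 1 + shift) % 100) + 1, st, "coding")
                     for gid, s, e, st in base]
            # keep intervals non-wrapping for the record model
            genes = [(gid, s, e, st, k) if s < e else (gid, s - 100, e, st, k)
                     for gid, s, e, st, k in genes]
            genes = [(gid, max(s, 0), e, st, k) for gid, s, e, st, k in genes]
            genome = make_genome("A" * 100, genes=genes)
            regions = ia.classify_intergenic(genome)
            counts.append(sorted(r.orientation_class for r in regions))
        assert counts[0] == counts[1]


class TestTURelation:
    def test_relations(self):
        genome = make_genome(
            "A" * 100,
            genes=[("g1", 0, 10, "+", "coding"), ("g2", 20, 30, "+", "coding"),
                   ("g3", 40, 50, "+", "coding"), ("g4", 60, 70, "-", "coding")],
            circular=False,
        )
        tus = [TURecord("tu1", ("g1", "g2"), "+"), TURecord("tu2", ("g3",), "+")]
        regions = ia.annotate_tu_relation(ia.classify_intergenic(genome), tus)
        by_pair = {(r.left_gene, r.right_gene): r for r in regions}
        assert by_pair[("g1", "g2")].tu_relation == "intra_tu"
        assert by_pair[("g2", "g3")].tu_relation == "inter_tu"
        assert by_pair[("g3", "g4")].tu_relation == "not_applicable"  # convergent


class TestRegionStats:
    def test_constant_profile(self):
        genome = two_gene_genome("+", "-", circular=False)
        regions = ia.classify_intergenic(genome)
        df = ia.region_profile_stats(regions, np.full(40, 2.5), 40)
        assert np.allclose(df["value"], 2.5)

    def test_single_region_min_statistic(self):
        genome = two_gene_genome("+", "+", circular=False)
        track = np.arange(40.0)
        df = ia.region_profile_stats(ia.classify_intergenic(genome), track, 40,
                                     statistic="min")
        assert df["value"].tolist() == [10.0]

    def test_planted_divergent_destabilization_separates_classes(self, rng):
        """Low values planted only in divergent gaps -> rank-test p < 0.01."""
        genes, pos = [], 0
        strands = (["-", "+"] * 30 + ["+", "-"] * 30)
        for i, s in enumerate(strands):
            genes.append((f"g{i:03d}", pos, pos + 10, s, "coding"))
            pos += 20
        genome = make_genome("A" * pos, genes=genes, circular=False)
        regions = ia.classify_intergenic(genome)
        track = np.full(pos, 10.0) + rng.normal(0, 0.5, pos)
        for r in regions:
            if r.orientation_class == "divergent":
                track[r.start: r.end] -= 3.0
        df = ia.region_profile_stats(regions, track, pos)
        div = df.loc[df.orientation_class == "divergent", "value"]
        conv = df.loc[df.orientation_class == "convergent", "value"]
        assert len(div) >= 25 and len(conv) >= 25
        assert div.mean() < conv.mean()
        assert sps.mannwhitneyu(div, conv).pvalue < 0.01


class TestPromoterWindows:
    def test_uniform_upstream_value(self):
        genome = two_gene_genome("+", "+", circular=False)
        vals = {v.gene_id: v for v in
                ia.promoter_window_values(genome, np.full(40, 4.0), window_bp=5)}
        assert vals["gR"].value == 4.0 and not vals["gR"].truncated
        # gL sits at the linear edge: no upstream sequence at all
        assert np.isnan(vals["gL"].value) and vals["gL"].truncated

    def test_minus_strand_window_is_downstream_in_forward_coords(self):
        genome = make_genome("A" * 60, genes=[("g", 10, 20, "-", "coding")])
        track = np.zeros(60)
        track[20:30] = 7.0
        vals = {v.gene_id: v.value for v in
                ia.promoter_window_values(genome, track, window_bp=10)}
        assert vals["g"] == 7.0

    def test_zero_window_rejected(self, toy_genome):
        with pytest.raises(ValueError):
            ia.promoter_window_values(toy_genome, np.zeros(10), window_bp=0)


class TestBimodality:
    def test_normal_sample_called_unimodal_reliably(self):
        unimodal = 0
        n_seeds = 30
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            out = ia.bimodality_assessment(r.normal(size=200), seed=seed,
                                           n_boot=200)
            unimodal += out["verdict"] == "unimodal"
        assert unimodal >= int(0.9 * n_seeds)

    def test_separated_mixture_called_bimodal(self):
        r = np.random.default_rng(1)
        x = np.concatenate([r.normal(-3, 1, 100), r.normal(3, 1, 100)])
        out = ia.bimodality_assessment(x, seed=1, n_boot=200)
        assert out["verdict"] == "bimodal"

    def test_identical_values_dip_zero(self):
        out = ia.bimodality_assessment(np.full(50, 3.3), seed=0, n_boot=50)
        assert out["dip_statistic"] == 0.0
        assert out["verdict"] == "unimodal"

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            ia.bimodality_assessment(np.arange(5), seed=0)

    def test_two_point_mass_dip_known_value(self):
        """The dip of an equal two-point mixture approaches 1/4."""
        x = np.array([0.0] * 200 + [1.0] * 200)
        assert ia.dip_statistic(x) == pytest.approx(0.25, abs=0.01)
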