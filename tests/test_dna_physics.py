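"""Physical-property calculators vs naive oracles and symmetry laws."""

import numpy as np
import pytest

from endoreg import dna_physics as dp
from endoreg import genome_model as gm
from conftest import make_genome, random_seq
import _oracles


@pytest.fixture(scope="module")
def stacking():
    return dp.load_dinucleotide_table("stacking_energy")


@pytest.fixture(scope="module")
def wedge():
    return dp.load_wedge_model()


class TestDinucleotideProfile:
    def test_homopolymer_is_constant(self):
        table = dp.DinucleotideTable(
            "toy", {d: (-1.0 if d == "AA" else 0.0)
                    for d in [a + b for a in "ACGT" for b in "ACGT"]}
        )
        assert np.allclose(dp.dinucleotide_profile("AAAA", table), -1.0)

    def test_single_dinucleotide(self):
        table = dp.DinucleotideTable(
            "toy", {d: (-2.0 if d == "AC" else 0.0)
                    for d in [a + b for a in "ACGT" for b in "ACGT"]}
        )
        assert np.allclose(dp.dinucleotide_profile("AC", table), -2.0)

    @pytest.mark.parametrize("table_name", ["stacking_energy", "propeller_twist"])
    def test_matches_naive_oracle_on_random_sequences(self, rng, table_name):
        table = dp.load_dinucleotide_table(table_name)
        for _ in range(20):
            seq = random_seq(rng, 200, gc=rng.uniform(0.2, 0.8))
            got = dp.dinucleotide_profile(seq, table)
            want = _oracles.naive_dinucleotide_profile(seq, table.values)
            np.testing.assert_allclose(got, want, atol=1e-12)

    def test_masked_positions(self):
        table = dp.load_dinucleotide_table("stacking_energy")
        prof = dp.dinucleotide_profile("ACNGT", table)
        assert np.isnan(prof[2])
        assert np.isfinite(prof[0]) and np.isfinite(prof[4])


class TestCurvature:
    def test_zero_wedges_give_zero_curvature(self):
        model = dp.WedgeModel(
            {d: (0.0, 0.0) for d in [a + b for a in "ACGT" for b in "ACGT"]}
        )
        prof = dp.curvature_profile("ACGT" * 20, model)
        assert np.allclose(prof, 0.0)

    def test_phased_a_tracts_curve_more_than_shuffled(self, rng, wedge):
        tract = ("AAAAA" + "GCGCG")  # 10 bp period ~ helical repeat
        phased = tract * 12
        shuffled = "".join(rng.permutation(list(phased)))
        c_ph = dp.curvature_profile(phased, wedge)
        c_sh = dp.curvature_profile(shuffled, wedge)
        assert np.nanmean(c_ph) > np.nanmean(c_sh)

    def test_reverse_complement_symmetry(self, rng, wedge):
        seq = random_seq(rng, 150)
        fwd = dp.curvature_profile(seq, wedge)
        rev = dp.curvature_profile(gm.revcomp(seq), wedge)
        np.testing.assert_allclose(fwd, rev[::-1], atol=1e-9)

    def test_matches_naive_oracle(self, rng, wedge):
        for _ in range(10):
            seq = random_seq(rng, 200)
            got = dp.curvature_profile(seq, wedge)
            want = _oracles.naive_curvature(
                seq, wedge.wedge_angles, wedge.helical_repeat, wedge.window_bp
            )
            np.testing.assert_allclose(got, want, atol=1e-9)

    def test_window_longer_than_linear_sequence_errors(self, wedge):
        with pytest.raises(ValueError, match="shorter"):
            dp.curvature_profile("ACGTACGT", wedge)


class TestWindowSmooth:
    def test_constant_vector(self):
        assert np.allclose(dp.window_smooth(np.full(30, 3.5), 7), 3.5)

    def test_simple_means_and_trailing_drop(self):
        np.testing.assert_allclose(dp.window_smooth([1, 2, 3, 4], 2), [1.5, 3.5])
        assert len(dp.window_smooth(np.arange(10.0), 3)) == 3

    def test_window_longer_than_profile_warns_empty(self):
        with pytest.warns(UserWarning):
            out = dp.window_smooth(np.arange(5.0), 10)
        assert out.size == 0

    def test_structural_profile_windowed_means(self, rng):
        vals = rng.normal(size=100)
        prof = dp.StructuralProfile("x", vals, 10)
        np.testing.assert_allclose(
            prof.windowed, vals.reshape(10, 10).mean(axis=1)
        )


class TestAlignedProfile:
    def test_single_gene_equals_oriented_slice(self):
        seq = "ACGT" * 50
        genome = make_genome(seq, genes=[("g", 100, 130, "+", "coding")])
        track = np.arange(len(seq), dtype=float)
        wins = gm.anchored_windows(genome, 10, 5)
        off, mean, n = dp.aligned_mean_profile(genome, track, wins)
        np.testing.assert_allclose(mean, np.arange(90, 105))
        assert n.tolist() == [1] * 15

    def test_opposite_strands_same_local_sequence_contribute_identically(self):
        # a gene and its mirror over reverse-complemented context
        seq = "AATTCCGGAATTCCGGAATT" * 10
        genome = make_genome(
            seq, genes=[("gp", 60, 80, "+", "coding")]
        )
        genome_m = make_genome(
            gm.revcomp(seq), genes=[("gm", len(seq) - 80, len(seq) - 60, "-", "coding")]
        )
        track_p = dp.dinucleotide_profile(
            seq, dp.load_dinucleotide_table("stacking_energy"), circular=True)
        track_m = dp.dinucleotide_profile(
            gm.revcomp(seq), dp.load_dinucleotide_table("stacking_energy"),
            circular=True)
        _, mean_p, _ = dp.aligned_mean_profile(
            genome, track_p, gm.anchored_windows(genome, 20, 10))
        _, mean_m, _ = dp.aligned_mean_profile(
            genome_m, track_m, gm.anchored_windows(genome_m, 20, 10))
        np.testing.assert_allclose(mean_p, mean_m, atol=1e-12)


class TestSIDD:
    def test_exhaustive_oracle_small_toy(self):
        """Thresholdless algorithm equals plain enumeration on a 30 bp toy."""
        seq = "GC" * 5 + "AT" * 5 + "GC" * 5
        params = dp.default_sidd_params(sigma=-0.06, energy_threshold_theta=None)
        got = dp.sidd_opening_probability(seq, params, circular=False)
        want = _oracles.exhaustive_sidd_p(seq, params)
        np.testing.assert_allclose(got, want, atol=1e-9)

    def test_sigma_zero_profile_at_ceiling(self):
        params = dp.default_sidd_params(sigma=0.0)
        with pytest.warns(UserWarning, match="all-ceiling"):
            g = dp.sidd_profile("GCAT" * 15, params, circular=False)
        assert np.allclose(g, params.ceiling)

    def test_opening_monotone_in_superhelical_density(self):
        seq = "GC" * 10 + "AT" * 10 + "GC" * 10
        totals = []
        for sigma in (0.0, -0.03, -0.06):
            params = dp.default_sidd_params(sigma=sigma,
                                            energy_threshold_theta=None)
            totals.append(
                dp.sidd_opening_probability(seq, params, circular=False).sum()
            )
        assert totals[0] < totals[1] < totals[2]

    def test_at_island_less_stable_than_gc_flanks(self):
        seq = "GC" * 10 + "AT" * 10 + "GC" * 10
        params = dp.default_sidd_params(sigma=-0.06, energy_threshold_theta=None)
        g = dp.sidd_profile(seq, params, circular=False)
        at = slice(20, 40)
        assert np.argmin(g) in range(20, 40)
        assert g[at].mean() < np.concatenate((g[:20], g[40:])).mean()

    def test_homopolymer_circle_translational_symmetry(self):
        params = dp.default_sidd_params(sigma=-0.06)
        p = dp.sidd_opening_probability("A" * 80, params, circular=True)
        assert p.max() - p.min() < 1e-9
        assert p.mean() > 0

    def test_windowed_long_sequence_matches_single_domain_in_interior(self, rng):
        """Interior values of the windowed path track a directly solved domain."""
        params = dp.default_sidd_params()
        seq = random_seq(rng, 3 * params.window_bp, gc=0.3)
        p_windowed = dp.sidd_opening_probability(seq, params, circular=False)
        assert np.all(np.isfinite(p_windowed))
        assert p_windowed.min() >= 0 and p_windowed.max() <= 1

    def test_invalid_parameterisations_rejected(self):
        with pytest.raises(ValueError):
            dp.SIDDParams(separation_energy={"AT": 1.5, "GC": 0.3})
        with pytest.raises(ValueError):
            dp.SIDDParams(energy_threshold_theta=-1.0)
        with pytest.raises(ValueError):
            dp.SIDDParams(max_run_length=400, window_bp=250)
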