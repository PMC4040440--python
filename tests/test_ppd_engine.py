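import numpy as np
import pytest

from genoprog import (
    PpdDistribution,
    ValidationError,
    exchangeable_model,
    ppd,
    ppd_distribution,
    ppd_many,
    scaled_posterior_ratios,
    sweep_locus_count,
    sweep_prior,
    sweep_relative_risk,
    threshold_fractions,
)
from genoprog.model_spec import DiseaseModel, make_locus

from conftest import (
    enumerate_ppd_distribution,
    random_heterogeneous_model,
    total_variation,
)


class TestPpd:
    def test_single_locus_bayes_rule(self, single_locus_model):
        # carrier: 0.2*0.1 / (0.2*0.1 + 0.8*0.05) = 0.02/0.06
        assert ppd(single_locus_model, [1]) == pytest.approx(1 / 3, abs=1e-12)
        # non-carrier: 0.2*0.9 / (0.2*0.9 + 0.8*0.95) = 0.18/0.94
        assert ppd(single_locus_model, [0]) == pytest.approx(0.18 / 0.94, abs=1e-12)

    def test_uninformative_loci_return_prior(self, null_model):
        for g in ([0] * 10, [1] * 10, [0, 1] * 5):
            assert ppd(null_model, g) == pytest.approx(0.2, abs=1e-12)

    @pytest.mark.parametrize("prior", [0.0, 1.0])
    def test_degenerate_prior_returned_exactly(self, prior):
        model = DiseaseModel(prior=prior, loci=(make_locus(0.05, 2.0),))
        assert ppd(model, [1]) == prior

    def test_length_mismatch_rejected(self, single_locus_model):
        with pytest.raises(ValidationError):
            ppd(single_locus_model, [1, 0])

    def test_vectorized_matches_scalar(self, single_locus_model):
        got = ppd_many(single_locus_model, np.array([[0], [1]]))
        assert got == pytest.approx([0.18 / 0.94, 1 / 3], abs=1e-12)


class TestPpdDistributionOracle:
    """Engine vs exhaustive 2^n enumeration (independent Bayes-rule oracle)."""

    @pytest.mark.parametrize("mode", ["control", "marginal_independent", "mixture"])
    def test_heterogeneous_models_match_enumeration(self, mode):
        rng = np.random.default_rng(7)
        model = random_heterogeneous_model(rng, 10, mode=mode)
        dist = ppd_distribution(model)
        s, m = enumerate_ppd_distribution(model, mode)
        assert total_variation(dist.support, dist.mass, s, m) < 1e-6

    @pytest.mark.parametrize("mode", ["control", "marginal_independent", "mixture"])
    def test_exchangeable_carrier_count_path_matches_enumeration(self, mode):
        model = exchangeable_model(8, 0.05, 2.0, 0.2, mode=mode)
        dist = ppd_distribution(model)
        s, m = enumerate_ppd_distribution(model, mode)
        assert total_variation(dist.support, dist.mass, s, m) < 1e-6

    def test_grid_convolution_matches_exact_fractions(self):
        """Force the binned DP on loci whose exact answer is known via the
        carrier-count path, and compare moments and tail fractions."""
        model = exchangeable_model(30, 0.05, 2.0, 0.2)
        exact = ppd_distribution(model, method="auto")
        grid = ppd_distribution(model, method="grid", resolution=4096)
        assert grid.mean() == pytest.approx(exact.mean(), abs=2e-4)
        assert grid.variance() == pytest.approx(exact.variance(), abs=2e-4)
        re, rg = threshold_fractions(exact), threshold_fractions(grid)
        assert rg.c2_fraction == pytest.approx(re.c2_fraction, abs=5e-3)
        assert rg.c1_fraction == pytest.approx(re.c1_fraction, abs=5e-3)

    def test_grid_requires_minimum_resolution(self):
        model = exchangeable_model(5, 0.05, 2.0, 0.2)
        with pytest.raises(ValidationError):
            ppd_distribution(model, method="grid", resolution=64)

    def test_monte_carlo_agrees_on_fractions(self):
        model = exchangeable_model(50, 0.05, 2.0, 0.2, mode="mixture")
        exact = threshold_fractions(ppd_distribution(model), 0.5, 0.05)
        mc = threshold_fractions(
            ppd_distribution(model, method="monte_carlo", seed=11), 0.5, 0.05
        )
        # 100k draws; 3 binomial SE on each fraction
        for a, b in [
            (exact.c1_fraction, mc.c1_fraction),
            (exact.c2_fraction, mc.c2_fraction),
        ]:
            se = np.sqrt(a * (1 - a) / 100_000)
            assert abs(a - b) <= 3 * se + 1e-12


class TestPpdDistributionProperties:
    def test_mass_conserved_and_support_ascending(self):
        dist = ppd_distribution(exchangeable_model(1000, 0.10, 1.45, 0.20))
        assert dist.mass.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(dist.support) > 0)
        assert dist.support[0] >= 0 and dist.support[-1] <= 1

    def test_single_locus_two_point_and_mode_agreement(self):
        model = exchangeable_model(1, 0.05, 2.0, 0.2)
        d_marg = ppd_distribution(model, mode="marginal_independent")
        d_mix = ppd_distribution(model, mode="mixture")
        assert d_marg.support.size == 2
        assert d_marg.support == pytest.approx(d_mix.support)
        assert d_marg.mass == pytest.approx(d_mix.mass, abs=1e-12)

    def test_mixture_mean_equals_prior(self):
        """Law of total expectation holds only over the generative mixture."""
        model = exchangeable_model(200, 0.05, 2.0, 0.2, mode="mixture")
        assert ppd_distribution(model).mean() == pytest.approx(0.2, abs=1e-9)

    def test_posterior_monotone_in_carrier_count(self):
        model = exchangeable_model(50, 0.05, 2.0, 0.2)
        k = np.arange(51)
        vals = np.array(
            [ppd(model, [1] * i + [0] * (50 - i)) for i in k]
        )
        assert np.all(np.diff(vals) > 0)

    def test_null_model_collapses_to_point_mass(self, null_model):
        dist = ppd_distribution(null_model)
        assert dist.support.size == 1
        assert dist.support[0] == pytest.approx(0.2, abs=1e-12)

    def test_rejects_oversized_models(self):
        model = exchangeable_model(2, 0.05, 2.0, 0.2)
        object.__setattr__(model, "loci", model.loci * 60_000)
        with pytest.raises(ValidationError):
            ppd_distribution(model)


class TestThresholdFractions:
    def test_null_model_in_neither_region(self, null_model):
        rep = threshold_fractions(ppd_distribution(null_model), 0.95, 0.05)
        assert (rep.c1_fraction, rep.c2_fraction, rep.neither_fraction) == (0, 0, 1)

    def test_strict_inequalities_exclude_mass_at_thresholds(self):
        dist = PpdDistribution(
            support=np.array([0.05, 0.5, 0.95]),
            mass=np.array([0.3, 0.4, 0.3]),
            population_mode="control",
            model_digest="x",
        )
        rep = threshold_fractions(dist, 0.95, 0.05)
        assert rep.c1_fraction == 0.0 and rep.c2_fraction == 0.0

    def test_matches_enumeration_sums(self):
        rng = np.random.default_rng(3)
        model = random_heterogeneous_model(rng, 3)
        s, m = enumerate_ppd_distribution(model)
        rep = threshold_fractions(ppd_distribution(model), 0.3, 0.15)
        assert rep.c1_fraction == pytest.approx(m[s > 0.3].sum(), abs=1e-12)
        assert rep.c2_fraction == pytest.approx(m[s < 0.15].sum(), abs=1e-12)

    def test_threshold_ordering_enforced(self, null_model):
        dist = ppd_distribution(null_model)
        with pytest.raises(ValidationError):
            threshold_fractions(dist, 0.05, 0.95)


class TestSweeps:
    def test_rr_one_gives_zero_fractions(self):
        df = sweep_relative_risk(100, 0.05, 0.2, [1.0])
        assert df.c1.iloc[0] == 0 and df.c2.iloc[0] == 0

    def test_penetrant_model_dominates_polygenic_c1(self):
        """Rare, high-effect variants yield far more actionably-high
        posteriors than the common weak-effect architecture."""
        poly = sweep_relative_risk(1000, 0.10, 0.20, np.arange(1.02, 1.81, 0.26))
        pen = sweep_relative_risk(100, 0.001, 0.20, [10, 100, 250, 400])
        assert pen.c1.max() > 10 * poly.c1.max()

    def test_prior_sweep_extremes_use_epsilon_limits(self):
        df = sweep_prior(100, 0.05, 2.0, [0.0, 0.5, 1.0])
        assert df.c2.iloc[0] > 0.99  # prior -> 0: almost everyone below tau_neg
        assert df.c1.iloc[2] > 0.99  # prior -> 1: almost everyone above tau_pos
        assert df.neither.iloc[1] > 0.5

    def test_variance_increases_with_locus_count(self):
        """Under the generative (mixture) population the posterior is a
        martingale in the information set, so its variance grows with the
        number of informative loci (toward prior*(1-prior))."""
        df = sweep_locus_count(0.05, 2.0, 0.20, [20, 100, 500, 1000], mode="mixture")
        assert np.all(np.diff(df.ppd_variance) > 0)

    def test_single_locus_variance_closed_form(self):
        df = sweep_locus_count(0.05, 2.0, 0.20, [1])
        p_hi, p_lo = 1 / 3, 0.18 / 0.94
        g_pop = 0.2 * 0.1 + 0.8 * 0.05
        mean = g_pop * p_hi + (1 - g_pop) * p_lo
        var = g_pop * (p_hi - mean) ** 2 + (1 - g_pop) * (p_lo - mean) ** 2
        assert df.ppd_variance.iloc[0] == pytest.approx(var, abs=1e-12)

    def test_rr_one_variance_zero_for_all_n(self):
        df = sweep_locus_count(0.05, 1.0, 0.20, [1, 10, 100])
        assert np.all(df.ppd_variance == 0)

    def test_nondescending_n_grid_rejected(self):
        with pytest.raises(ValidationError):
            sweep_locus_count(0.05, 2.0, 0.2, [10, 10])


class TestScaledPosteriorRatios:
    def test_identical_genotypes_scale_to_one(self, single_locus_model):
        assert scaled_posterior_ratios(
            single_locus_model, [[1], [1], [1]]
        ) == pytest.approx([1, 1, 1])

    def test_matches_posterior_ratio_arithmetic(self):
        dist = PpdDistribution(
            support=np.array([0.01, 0.41]),
            mass=np.array([0.5, 0.5]),
            population_mode="control",
            model_digest="x",
        )
        assert dist.support[1] / dist.support[0] == pytest.approx(41.0)

    def test_all_combinations_against_enumeration(self):
        import itertools

        rng = np.random.default_rng(5)
        model = random_heterogeneous_model(rng, 3)
        combos = list(itertools.product((0, 1), repeat=3))
        srr = scaled_posterior_ratios(model, combos)
        ppds = np.array([ppd(model, c) for c in combos])
        assert srr == pytest.approx(ppds / ppds.min())
        assert srr.min() == 1.0

    def test_empty_list_rejected(self, single_locus_model):
        with pytest.raises(ValidationError):
            scaled_posterior_ratios(single_locus_model, [])
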