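"""Estimator correctness against hand-computed and independent oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import metabomr as mm
from metabomr import estimators as est


def wls_origin_oracle(iset):
    """Independent IVW oracle: normal equations of WLS through the origin."""
    bx, by, sy = iset.beta_exp, iset.beta_out, iset.se_out
    w = 1.0 / sy**2
    theta = float(np.sum(w * bx * by) / np.sum(w * bx**2))
    se = float(np.sum(w * bx**2) ** -0.5)
    return theta, se


class TestWaldRatio:
    def test_hand_example(self):
        inst = mm.HarmonizedInstrument("rs1", 0.10, 0.02, 0.05, 0.02)
        e = mm.wald_ratio(inst)
        assert e.theta == pytest.approx(0.5)
        assert e.se == pytest.approx(0.2)
        assert e.or_value == pytest.approx(1.6487, abs=1e-4)
        assert e.ci_low < e.or_value < e.ci_high

    def test_null_outcome(self):
        e = mm.wald_ratio(mm.HarmonizedInstrument("rs1", 0.10, 0.02, 0.0, 0.02))
        assert (e.theta, e.or_value, e.pvalue) == (0.0, 1.0, 1.0)

    def test_ratio_invariant_to_joint_sign_flip(self):
        a = mm.wald_ratio(mm.HarmonizedInstrument("rs1", 0.1, 0.02, 0.05, 0.02))
        b = mm.wald_ratio(mm.HarmonizedInstrument("rs1", -0.1, 0.02, -0.05, 0.02))
        assert a.theta == pytest.approx(b.theta)
        assert a.se == pytest.approx(b.se)

    def test_zero_exposure_effect_errors(self):
        with pytest.raises(mm.EstimationError):
            mm.wald_ratio(mm.HarmonizedInstrument("rs1", 0.0, 0.02, 0.05, 0.02))


class TestIVW:
    def test_two_instrument_hand_example(self, two_snp_set):
        e = mm.ivw(two_snp_set, "fixed")
        assert e.theta == pytest.approx(1.0)
        assert e.se == pytest.approx(1 / math.sqrt(2))

    def test_matches_normal_equation_oracle(self, random_sets):
        for iset in random_sets:
            e = mm.ivw(iset, "fixed")
            theta, se = wls_origin_oracle(iset)
            assert e.theta == pytest.approx(theta, rel=1e-10)
            assert e.se == pytest.approx(se, rel=1e-10)

    def test_exact_fit_has_zero_q_and_equal_ses(self):
        iset = mm.InstrumentSet.from_arrays(
            [0.1, 0.2, 0.4], [0.01] * 3, [0.05, 0.10, 0.20], [1.0, 0.5, 2.0]
        )
        fixed = mm.ivw(iset, "fixed")
        random = mm.ivw(iset, "random")
        assert fixed.theta == pytest.approx(0.5)
        assert random.se == pytest.approx(fixed.se)  # inflation floored at 1

    def test_random_inflates_when_heterogeneous(self):
        iset = mm.InstrumentSet.from_arrays(
            [1.0, 1.0, 1.0], [0.01] * 3, [0.0, 1.0, 5.0], [0.1, 0.1, 0.1]
        )
        assert mm.ivw(iset, "random").se > mm.ivw(iset, "fixed").se

    def test_auto_mode_follows_heterogeneity(self, two_snp_set):
        assert mm.ivw(two_snp_set, "auto").method == "ivw_fixed"  # Q p ~ 0.48
        het = mm.InstrumentSet.from_arrays(
            [1.0, 1.0, 1.0], [0.01] * 3, [0.0, 1.0, 5.0], [0.1, 0.1, 0.1]
        )
        assert mm.ivw(het, "auto").method == "ivw_random"

    def test_single_instrument_directed_to_wald(self):
        iset = mm.InstrumentSet.from_arrays([0.1], [0.01], [0.05], [0.02])
        with pytest.raises(mm.EstimationError, match="wald"):
            mm.ivw(iset)

    def test_one_snp_formulas_coincide_with_wald(self):
        """IVW normal equations at k=1 reduce to the Wald ratio."""
        bx, sx, by, sy = 0.1, 0.02, 0.05, 0.03
        theta = (by / sy**2 * bx) / (bx**2 / sy**2)
        se = (bx**2 / sy**2) ** -0.5
        wald = mm.wald_ratio(mm.HarmonizedInstrument("rs1", bx, sx, by, sy))
        assert theta == pytest.approx(wald.theta)
        assert se == pytest.approx(wald.se)


class TestMaximumLikelihood:
    def test_tiny_exposure_se_recovers_ivw(self, random_sets):
        for iset in random_sets[:10]:
            tight = mm.InstrumentSet.from_arrays(
                iset.beta_exp, np.full(iset.n_snp, 1e-8),
                iset.beta_out, iset.se_out,
            )
            ml = mm.maximum_likelihood(tight)
            assert ml.theta == pytest.approx(mm.ivw(tight).theta, abs=1e-4)

    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(42)
        iset = mm.InstrumentSet.from_arrays(
            beta_exp=rng.normal(0.08, 0.02, 5),
            se_exp=rng.uniform(0.005, 0.02, 5),
            beta_out=rng.normal(0.02, 0.02, 5),
            se_out=rng.uniform(0.01, 0.03, 5),
        )
        ml = mm.maximum_likelihood(iset)
        grid = np.arange(-2.0, 2.0 + 1e-9, 1e-4)
        nll = [est._profile_negloglik(t, iset.beta_exp, iset.se_exp**2,
                                      iset.beta_out, iset.se_out**2)
               for t in grid]
        theta_grid = grid[int(np.argmin(nll))]
        assert ml.theta == pytest.approx(theta_grid, abs=1e-4)

    def test_common_ratio_with_tiny_ses(self):
        iset = mm.InstrumentSet.from_arrays(
            [0.1, 0.2, 0.3], [1e-5] * 3, [0.07, 0.14, 0.21], [1e-5] * 3
        )
        assert mm.maximum_likelihood(iset).theta == pytest.approx(0.7, abs=1e-6)

    def test_requires_two_instruments(self):
        iset = mm.InstrumentSet.from_arrays([0.1], [0.01], [0.05], [0.02])
        with pytest.raises(mm.EstimationError):
            mm.maximum_likelihood(iset)


class TestWeightedMedianStatistic:
    @pytest.mark.parametrize(
        "thetas, weights, expected",
        [
            ((1.0, 2.0, 3.0), (1.0, 1.0, 1.0), 2.0),
            ((1.0, 2.0, 3.0), (0.5, 0.25, 0.25), 5 / 3),
            ((4.2,), (1.0,), 4.2),
            ((3.0, 1.0, 2.0), (1.0, 1.0, 1.0), 2.0),  # order-free
            ((1.0, 2.0), (3.0, 1.0), 1.25),  # s grid (0.375, 0.875)
        ],
    )
    def test_hand_cases(self, thetas, weights, expected):
        assert mm.weighted_median_statistic(thetas, weights) == \
            pytest.approx(expected)

    def test_positive_weights_required(self):
        with pytest.raises(ValueError):
            mm.weighted_median_statistic([1.0, 2.0], [1.0, 0.0])

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(-1000, 1000), min_size=1, max_size=12,
                 unique=True).map(lambda xs: [x / 100 for x in xs]),
        st.data(),
    )
    def test_bounded_by_extremes_and_scale_shift(self, thetas, data):
        weights = data.draw(st.lists(
            st.floats(0.1, 5), min_size=len(thetas), max_size=len(thetas)))
        v = mm.weighted_median_statistic(thetas, weights)
        assert min(thetas) - 1e-12 <= v <= max(thetas) + 1e-12
        shifted = mm.weighted_median_statistic([t + 3 for t in thetas], weights)
        assert shifted == pytest.approx(v + 3, abs=1e-9)


class TestMedianEstimators:
    def iset(self, seed=1, k=6):
        rng = np.random.default_rng(seed)
        bx = rng.uniform(0.05, 0.12, k)
        return mm.InstrumentSet.from_arrays(
            bx, rng.uniform(0.004, 0.008, k),
            0.3 * bx + rng.normal(0, 0.004, k), rng.uniform(0.004, 0.008, k),
        )

    def test_common_ratio_point_estimate(self):
        iset = mm.InstrumentSet.from_arrays(
            [0.1, 0.2, 0.3], [0.01] * 3, [0.05, 0.10, 0.15], [0.01, 0.02, 0.03]
        )
        for variant in ("simple", "weighted"):
            e = mm.median_estimators(iset, variant, n_boot=50, seed=0)
            assert e.theta == pytest.approx(0.5)

    def test_simple_equals_weighted_under_equal_weights(self):
        # equal ratio weights: identical beta_exp magnitudes and outcome SEs
        iset = mm.InstrumentSet.from_arrays(
            [0.1, 0.1, 0.1], [0.01] * 3, [0.03, 0.05, 0.09], [0.02] * 3
        )
        s = mm.median_estimators(iset, "simple", n_boot=10, seed=0)
        w = mm.median_estimators(iset, "weighted", n_boot=10, seed=0)
        assert s.theta == pytest.approx(w.theta)

    def test_bootstrap_se_reproducible(self):
        iset = self.iset()
        a = mm.median_estimators(iset, "weighted", n_boot=200, seed=7)
        b = mm.median_estimators(iset, "weighted", n_boot=200, seed=7)
        assert a == b
        c = mm.median_estimators(iset, "weighted", n_boot=200, seed=8)
        assert c.se != a.se

    def test_gating_below_three(self):
        iset = mm.InstrumentSet.from_arrays([0.1, 0.2], [0.01] * 2,
                                            [0.05, 0.1], [0.02] * 2)
        with pytest.raises(mm.EstimationError):
            mm.median_estimators(iset, "weighted")


class TestMREgger:
    def test_exact_line(self, exact_line_set):
        slope, intercept = mm.mr_egger(exact_line_set)
        assert intercept.intercept == pytest.approx(0.1)
        assert slope.theta == pytest.approx(0.5)

    def test_intercept_zero_regression_matches_ivw(self, random_sets):
        """Forcing the intercept out reproduces the IVW slope exactly."""
        import statsmodels.api as sm
        for iset in random_sets[:10]:
            sign = np.where(iset.beta_exp < 0, -1.0, 1.0)
            fit = sm.WLS(iset.beta_out * sign, (iset.beta_exp * sign)[:, None],
                         weights=1 / iset.se_out**2).fit()
            assert fit.params[0] == pytest.approx(mm.ivw(iset).theta, rel=1e-10)

    def test_orientation_invariance(self, exact_line_set):
        flipped = mm.InstrumentSet.from_arrays(
            -exact_line_set.beta_exp, exact_line_set.se_exp,
            -exact_line_set.beta_out, exact_line_set.se_out,
        )
        a = mm.mr_egger(exact_line_set)[0]
        b = mm.mr_egger(flipped)[0]
        assert a.theta == pytest.approx(b.theta)

    def test_collinear_exposure_errors(self):
        iset = mm.InstrumentSet.from_arrays([0.1] * 3, [0.01] * 3,
                                            [0.0, 0.1, 0.2], [0.1] * 3)
        with pytest.raises(mm.EstimationError, match="collinear"):
            mm.mr_egger(iset)

    def test_no_pleiotropy_intercept_rarely_rejected(self):
        """Balanced truth: intercept test should hold its 5% size."""
        nonrejected = 0
        reps = 200
        for rep in range(reps):
            cfg = mm.SimulationConfig(
                k_instruments=50, theta=0.1, seed=mm.derive_seed(404, rep)
            )
            exposure, outcome, truth = mm.simulate_sumstats(cfg)
            iset = mm.instrument_set_from_truth(exposure, outcome, truth)
            _, intercept = mm.mr_egger(iset)
            nonrejected += intercept.pvalue > 0.05
        assert nonrejected >= 0.90 * reps


class TestGatedMethods:
    def single(self):
        return mm.InstrumentSet.from_arrays([0.1], [0.01], [0.05], [0.02])

    def of_size(self, k):
        rng = np.random.default_rng(k)
        bx = rng.uniform(0.05, 0.15, k)
        return mm.InstrumentSet.from_arrays(
            bx, rng.uniform(0.005, 0.01, k),
            0.2 * bx + rng.normal(0, 0.01, k), rng.uniform(0.01, 0.02, k),
        )

    def test_single_instrument_wald_only(self):
        out = mm.run_gated_methods(self.single())
        assert [e.method for e in out] == ["wald_ratio"]

    def test_two_instruments_ivw_and_ml(self):
        methods = [e.method for e in mm.run_gated_methods(self.of_size(2))]
        assert methods == ["ivw_fixed", "ivw_random", "maximum_likelihood"]

    def test_three_instruments_add_medians_and_egger(self):
        methods = [e.method for e in mm.run_gated_methods(self.of_size(3), seed=1)]
        assert methods == [
            "ivw_fixed", "ivw_random", "maximum_likelihood",
            "simple_median", "weighted_median", "mr_egger",
        ]

    def test_four_instruments_all_method_families(self):
        methods = {e.method for e in mm.run_gated_methods(self.of_size(4), seed=1)}
        assert methods == {
            "ivw_fixed", "ivw_random", "maximum_likelihood",
            "simple_median", "weighted_median", "mr_egger",
        }

    def test_strict_gating_confines_small_sets_to_ivw(self):
        for k in (2, 3):
            methods = [e.method for e in mm.run_gated_methods(
                self.of_size(k), gating_mode="ivw_only_below_4")]
            assert methods == ["ivw_fixed", "ivw_random"]
        methods = {e.method for e in mm.run_gated_methods(
            self.of_size(4), gating_mode="ivw_only_below_4", seed=1)}
        assert "weighted_median" in methods and "mr_egger" in methods


class TestScaleEquivariance:
    @pytest.mark.parametrize("c", [0.5, 2.0, 10.0])
    def test_exposure_rescale_divides_theta(self, c):
        iset = TestGatedMethods().of_size(5)
        scaled = mm.InstrumentSet.from_arrays(
            c * iset.beta_exp, c * iset.se_exp, iset.beta_out, iset.se_out
        )
        for fn in (lambda s: mm.ivw(s), mm.maximum_likelihood,
                   lambda s: mm.mr_egger(s)[0],
                   lambda s: mm.median_estimators(s, "weighted", 100, 3)):
            base = fn(iset).theta
            assert fn(scaled).theta == pytest.approx(base / c, rel=1e-6)

    @pytest.mark.parametrize("c", [0.5, 3.0])
    def test_outcome_rescale_multiplies_theta(self, c):
        iset = TestGatedMethods().of_size(5)
        scaled = mm.InstrumentSet.from_arrays(
            iset.beta_exp, iset.se_exp, c * iset.beta_out, c * iset.se_out
        )
        for fn in (lambda s: mm.ivw(s), mm.maximum_likelihood,
                   lambda s: mm.mr_egger(s)[0],
                   lambda s: mm.median_estimators(s, "weighted", 100, 3)):
            base = fn(iset).theta
            assert fn(scaled).theta == pytest.approx(c * base, rel=1e-6)
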