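"""Estimator correctness against independent oracles and exact identities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from summr import (
    SummarySet,
    ivw,
    median_estimator,
    mode_estimator,
    mr_egger,
    ratio_density,
    ratio_estimates,
)
from summr.exceptions import ConfigurationError, ValidationError

# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def wls_normal_equations(x, y, w):
    """Closed-form WLS of y on [1, x]: solve the 2x2 normal equations."""
    X = np.column_stack([np.ones_like(x), x])
    A = X.T @ (w[:, None] * X)
    b = X.T @ (w * y)
    return np.linalg.solve(A, b)  # (intercept, slope)


def weighted_median_grid_inversion(ratios, weights, n_grid=2_000_001):
    """Invert the piecewise-linear percentile function on a dense grid."""
    order = np.argsort(ratios)
    r, w = ratios[order], weights[order] / weights.sum()
    p = 100.0 * (np.cumsum(w) - w / 2.0)
    if 50.0 <= p[0]:
        return r[0]
    if 50.0 >= p[-1]:
        return r[-1]
    grid = np.linspace(r[0], r[-1], n_grid)
    pg = np.interp(grid, r, p)
    return grid[np.argmin(np.abs(pg - 50.0))]


def mode_brute_force(ratios, weights, phi, n_grid=100_000):
    """Evaluate the weighted Gaussian kernel density directly and take argmax."""
    j = len(ratios)
    sd = np.std(ratios, ddof=1)
    mad = stats.median_abs_deviation(ratios, scale="normal")
    h = phi * 0.9 * min(s for s in (sd, mad) if s > 0) * j ** (-0.2)
    grid = np.linspace(ratios.min() - 2 * h, ratios.max() + 2 * h, n_grid)
    dens = np.zeros_like(grid)
    for rj, wj in zip(ratios, weights / weights.sum()):
        dens += wj * np.exp(-0.5 * ((grid - rj) / h) ** 2)
    return grid[np.argmax(dens)], h


# ---------------------------------------------------------------------------
# IVW
# ---------------------------------------------------------------------------

class TestIVW:
    def test_single_variant_reduces_to_ratio(self):
        data = SummarySet.from_arrays([0.2], [0.01], [0.1], [0.05])
        est = ivw(data, model="fixed")
        assert est.estimate == pytest.approx(0.5, abs=1e-15)
        assert est.se == pytest.approx(0.05 / 0.2, abs=1e-15)

    def test_random_effects_falls_back_at_j1(self):
        data = SummarySet.from_arrays([0.2], [0.01], [0.1], [0.05])
        with pytest.warns(UserWarning, match="fixed"):
            est = ivw(data, model="multiplicative_random")
        assert est.method == "ivw_fe"

    def test_matches_weighted_mean_of_ratios(self, toy5):
        """Brute force: w_j = bx_j^2 / sy_j^2 applied to each ratio."""
        w = toy5.beta_exposure**2 / toy5.se_outcome**2
        r = toy5.beta_outcome / toy5.beta_exposure
        expected = np.sum(w * r) / np.sum(w)
        for model in ("fixed", "multiplicative_random"):
            assert ivw(toy5, model=model).estimate == pytest.approx(expected, rel=1e-12)

    def test_point_estimate_invariant_to_uniform_sy_rescale(self, toy5):
        scaled = SummarySet.from_arrays(
            toy5.beta_exposure, toy5.se_exposure,
            toy5.beta_outcome, 7.3 * toy5.se_outcome, toy5.variant_ids,
        )
        assert ivw(scaled).estimate == pytest.approx(ivw(toy5).estimate, rel=1e-12)

    def test_random_effects_never_tighter_than_fixed(self, random_set):
        for seed in range(5):
            data = random_set(20, seed)
            assert ivw(data).se >= ivw(data, model="fixed").se - 1e-15


# ---------------------------------------------------------------------------
# MR-Egger
# ---------------------------------------------------------------------------

class TestEgger:
    def test_requires_three_variants(self):
        data = SummarySet.from_arrays([0.1, 0.2], [0.01] * 2, [0.05, 0.1], [0.01] * 2)
        with pytest.raises(ValidationError, match="3 variants"):
            mr_egger(data)

    def test_collinear_points_fit_exactly(self):
        """Points on an exact line: intercept a, slope b, scale at its floor."""
        a, b = 0.02, 0.4
        bx = np.array([0.05, 0.10, 0.20])
        data = SummarySet.from_arrays(bx, [0.01] * 3, a + b * bx, [0.01, 0.02, 0.03])
        fit = mr_egger(data)
        assert fit.intercept.estimate == pytest.approx(a, abs=1e-12)
        assert fit.slope.estimate == pytest.approx(b, abs=1e-12)
        # residual scale floored at 1 -> SEs equal the unit-scale (fixed) SEs
        fit_fe = mr_egger(data, fixed_se=True)
        assert fit.slope.se == pytest.approx(fit_fe.slope.se, rel=1e-12)

    def test_matches_normal_equations_oracle(self, random_set):
        for seed in range(10):
            data = random_set(8, seed)
            fit = mr_egger(data)
            w = 1.0 / data.se_outcome**2
            a, b = wls_normal_equations(data.beta_exposure, data.beta_outcome, w)
            assert fit.intercept.estimate == pytest.approx(a, abs=1e-10)
            assert fit.slope.estimate == pytest.approx(b, abs=1e-10)

    def test_matches_statsmodels_wls(self, random_set):
        """Independent route: statsmodels WLS coefficients and SE structure."""
        sm = pytest.importorskip("statsmodels.api")
        data = random_set(12, 3)
        w = 1.0 / data.se_outcome**2
        res = sm.WLS(
            data.beta_outcome, sm.add_constant(data.beta_exposure), weights=w
        ).fit()
        fit_fe = mr_egger(data, fixed_se=True)
        assert fit_fe.intercept.estimate == pytest.approx(res.params[0], rel=1e-10)
        assert fit_fe.slope.estimate == pytest.approx(res.params[1], rel=1e-10)
        # fixed SEs == statsmodels SEs stripped of the estimated residual scale
        assert fit_fe.slope.se == pytest.approx(
            res.bse[1] / np.sqrt(res.scale), rel=1e-10
        )
        fit = mr_egger(data)
        assert fit.slope.se == pytest.approx(
            fit_fe.slope.se * max(1.0, np.sqrt(res.scale)), rel=1e-10
        )

    def test_zero_intercept_refit_equals_ivw(self, random_set):
        """Constraining the Egger intercept to the origin recovers IVW."""
        for seed in range(5):
            data = random_set(15, seed)
            w = 1.0 / data.se_outcome**2
            slope_origin = np.sum(w * data.beta_exposure * data.beta_outcome) / np.sum(
                w * data.beta_exposure**2
            )
            assert slope_origin == pytest.approx(ivw(data).estimate, abs=1e-10)

    def test_positive_exposure_orientation_invariant_to_recoding(self, random_set):
        data = random_set(10, 7)
        flip = np.ones(10)
        flip[::2] = -1.0
        recoded = SummarySet.from_arrays(
            flip * data.beta_exposure, data.se_exposure,
            flip * data.beta_outcome, data.se_outcome, data.variant_ids,
        )
        a = mr_egger(data, orient="positive_exposure")
        b = mr_egger(recoded, orient="positive_exposure")
        assert a.slope.estimate == pytest.approx(b.slope.estimate, rel=1e-12)
        assert a.intercept.estimate == pytest.approx(b.intercept.estimate, rel=1e-12)


# ---------------------------------------------------------------------------
# median estimators
# ---------------------------------------------------------------------------

def _set_with_ratios(ratios, ratio_se=None):
    """Build a SummarySet whose ratio estimates/SEs are exactly as given."""
    ratios = np.asarray(ratios, dtype=float)
    n = len(ratios)
    bx = np.ones(n)
    ratio_se = np.ones(n) if ratio_se is None else np.asarray(ratio_se, dtype=float)
    return SummarySet.from_arrays(bx, np.full(n, 0.01), ratios, ratio_se)


class TestMedian:
    def test_odd_simple_median_is_middle_value(self):
        data = _set_with_ratios([1.0, 2.0, 10.0])
        est = median_estimator(data, variant="simple", n_boot=2, seed=1)
        assert est.estimate == pytest.approx(2.0, abs=1e-12)

    def test_even_equal_weights_interpolates_midpoint(self):
        data = _set_with_ratios([1.0, 2.0, 3.0, 10.0])
        est = median_estimator(data, variant="simple", n_boot=2, seed=1)
        assert est.estimate == pytest.approx(2.5, abs=1e-12)

    def test_matches_grid_inversion_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            ratios = rng.normal(0.2, 1.0, 6)
            ratio_se = rng.uniform(0.2, 2.0, 6)
            data = _set_with_ratios(ratios, ratio_se)
            est = median_estimator(data, variant="weighted", n_boot=2, seed=5)
            oracle = weighted_median_grid_inversion(ratios, 1.0 / ratio_se**2)
            assert est.estimate == pytest.approx(oracle, abs=1e-6)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        ratios=st.lists(
            st.floats(-5, 5, allow_nan=False), min_size=2, max_size=9, unique=True
        )
    )
    def test_equal_weight_weighted_equals_simple(self, ratios):
        """With all ratio variances equal the weighted median is the simple one."""
        data = _set_with_ratios(ratios)  # unit ratio SEs -> equal weights
        simple = median_estimator(data, variant="simple", n_boot=2, seed=3)
        weighted = median_estimator(data, variant="weighted", n_boot=2, seed=3)
        assert weighted.estimate == pytest.approx(simple.estimate, abs=1e-12)

    def test_estimate_bounded_by_ratio_extremes(self, random_set):
        for seed in range(5):
            data = random_set(9, seed)
            r = [x[1] for x in ratio_estimates(data)]
            for variant in ("simple", "weighted", "penalized"):
                est = median_estimator(data, variant=variant, n_boot=2, seed=seed)
                assert min(r) - 1e-12 <= est.estimate <= max(r) + 1e-12

    def test_penalized_downweights_outlier(self):
        """A heterogeneous outlier drags the weighted median but not the penalized one."""
        # outlier carries ~42% of the weight: enough to pull the weighted
        # median off the cluster centre, not enough to capture it outright
        ratios = [0.08, 0.09, 0.10, 0.11, 0.12, 1.0]
        ratio_se = [0.02] * 5 + [1.0 / np.sqrt(9000.0)]
        data = _set_with_ratios(ratios, ratio_se)
        weighted = median_estimator(data, variant="weighted", n_boot=2, seed=1)
        penalized = median_estimator(data, variant="penalized", n_boot=2, seed=1)
        assert abs(penalized.estimate - 0.10) < abs(weighted.estimate - 0.10)

    def test_bootstrap_seeded_and_validated(self, toy5):
        a = median_estimator(toy5, n_boot=50, seed=9)
        b = median_estimator(toy5, n_boot=50, seed=9)
        assert a == b
        with pytest.raises(ConfigurationError):
            median_estimator(toy5, n_boot=0, seed=9)
        with pytest.raises(ConfigurationError):
            median_estimator(toy5, n_boot=10)


# ---------------------------------------------------------------------------
# mode estimator
# ---------------------------------------------------------------------------

class TestMode:
    def test_identical_ratios_return_common_value(self):
        data = SummarySet.from_arrays(
            [0.1, 0.2, 0.4], [0.01] * 3, [0.05, 0.10, 0.20], [0.01] * 3
        )
        est = mode_estimator(data, seed=1, n_boot=5)
        assert est.estimate == pytest.approx(0.5, abs=1e-12)

    @pytest.mark.parametrize("weighted", [False, True])
    def test_matches_brute_force_density_argmax(self, weighted):
        rng = np.random.default_rng(23)
        for _ in range(10):
            ratios = rng.normal(0.3, 0.5, 7)
            ratio_se = rng.uniform(0.1, 1.0, 7)
            data = _set_with_ratios(ratios, ratio_se)
            est = mode_estimator(data, weighted=weighted, phi=1.0, n_boot=2, seed=4)
            w = 1.0 / ratio_se**2 if weighted else np.ones(7)
            oracle, h = mode_brute_force(ratios, w, phi=1.0)
            step = (ratios.max() - ratios.min() + 4 * h) / (10_000 - 1)
            assert est.estimate == pytest.approx(oracle, abs=step)

    def test_density_plot_source_equals_estimator(self, random_set):
        data = random_set(9, 2)
        _, _, mode = ratio_density(data, phi=1.0, weighted=True)
        est = mode_estimator(data, seed=1, n_boot=2)
        assert est.estimate == mode

    def test_estimate_bounded_by_ratio_extremes(self, random_set):
        for seed in range(5):
            data = random_set(8, seed)
            r = [x[1] for x in ratio_estimates(data)]
            est = mode_estimator(data, seed=seed, n_boot=2)
            assert min(r) - 1e-12 <= est.estimate <= max(r) + 1e-12

    def test_recovers_truth_when_invalid_majority_shares_pleiotropy(self):
        """Zero-modal-pleiotropy robustness: 60% invalid variants with one
        shared direct effect spread their ratios over a continuum, while the
        40% valid variants pile up at the true effect; a sharp bandwidth
        (phi=0.25, unweighted) finds the valid spike where IVW is swamped."""
        true_beta = 0.1
        modes, ivws = [], []
        n_rep = 60
        for rep in range(n_rep):
            rng = np.random.default_rng(50_000 + rep)
            j, n_invalid = 50, 30
            gamma = rng.uniform(0.05, 0.15, j)
            alpha = np.zeros(j)
            alpha[:n_invalid] = 0.1  # one shared pleiotropy value
            sx = rng.uniform(0.5, 1.5, j) * 0.002
            sy = rng.uniform(0.5, 1.5, j) * 0.002
            bx = rng.normal(gamma, sx)
            by = rng.normal(true_beta * gamma + alpha, sy)
            data = SummarySet.from_arrays(bx, sx, by, sy)
            modes.append(
                mode_estimator(data, weighted=False, phi=0.25, n_boot=2, seed=rep).estimate
            )
            ivws.append(ivw(data).estimate)
        modes = np.asarray(modes)
        mcse = modes.std(ddof=1) / np.sqrt(n_rep)
        assert abs(modes.mean() - true_beta) < 3 * mcse
        assert abs(np.mean(ivws) - true_beta) > 0.1  # IVW grossly biased

    def test_parameter_validation(self, toy5):
        with pytest.raises(ConfigurationError):
            mode_estimator(toy5, phi=0.0, seed=1)
        with pytest.raises(ValidationError):
            mode_estimator(SummarySet(toy5.records[:2]), seed=1)


# ---------------------------------------------------------------------------
# cross-estimator properties
# ---------------------------------------------------------------------------

def test_all_estimators_invariant_under_joint_sign_flip(random_set):
    """Recoding alleles (flipping both betas) never moves IVW/median/mode."""
    data = random_set(11, 19)
    flip = np.ones(11)
    flip[[1, 4, 7]] = -1.0
    recoded = SummarySet.from_arrays(
        flip * data.beta_exposure, data.se_exposure,
        flip * data.beta_outcome, data.se_outcome, data.variant_ids,
    )
    assert ivw(recoded).estimate == pytest.approx(ivw(data).estimate, rel=1e-12)
    for variant in ("simple", "weighted", "penalized"):
        a = median_estimator(data, variant=variant, n_boot=2, seed=2).estimate
        b = median_estimator(recoded, variant=variant, n_boot=2, seed=2).estimate
        assert a == pytest.approx(b, rel=1e-12)
    a = mode_estimator(data, n_boot=2, seed=2).estimate
    b = mode_estimator(recoded, n_boot=2, seed=2).estimate
    assert a == pytest.approx(b, rel=1e-12)
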