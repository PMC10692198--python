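"""Objective algebra, hyperparameter heuristics, dispersion estimation,
MAP fitting behavior and the chromosome-arm bootstrap."""

import numpy as np
import pytest

from recne import (DemographicModel, FitConfig, bootstrap_ci,
                   estimate_dispersion_ibd, expected_ibd_density, expected_ld,
                   fit_map, neg_log_pseudo_posterior, rmsle, scenario,
                   select_power)
from recne.inference import (_IBDData, _LDData, _TrajectoryOp,
                             _single_exponential_fit)
from recne.ld import BinnedLD

from test_filters import make_binned_ld, make_hist


def _exact_ld_data(model, n_regions=12, n_hap=200.0, var=1e-8):
    """BinnedLD whose observations sit exactly at the model expectation."""
    edges = np.arange(0.5, 30.1, 0.5)
    centers = 0.5 * (edges[:-1] + edges[1:])
    mu = expected_ld(model, centers, n_hap)
    y = np.tile(mu, (n_regions, 1))
    b = len(centers)
    from recne.ld import finite_sample_baseline

    base = np.full((n_regions, b), finite_sample_baseline(n_hap, n_hap))
    return BinnedLD(np.arange(1, n_regions + 1), edges, y,
                    np.full((n_regions, b), 500, dtype=np.int64),
                    np.full((n_regions, b), var), base, n_hap)


def _noisy_ld_data(model, rng, n_regions=15, n_hap=200.0, noise=2e-5):
    ld = _exact_ld_data(model, n_regions, n_hap)
    ld.y = ld.y + rng.normal(0, noise, size=ld.y.shape)
    return ld


class TestObjective:
    def test_linear_in_power_exponent(self):
        model = scenario("constant").model
        ld = _exact_ld_data(model)
        ld.y += 1e-5  # shift so the nll is nonzero
        op = _TrajectoryOp(model.grid_times, 125, 1250)
        data = _LDData(ld, op)
        theta = model.log_ne
        full = neg_log_pseudo_posterior(theta, data, 1.0, 0.0)
        half = neg_log_pseudo_posterior(theta, data, 0.5, 0.0)
        assert half == pytest.approx(full / 2.0, rel=1e-12)

    def test_truth_is_stationary_on_exact_data(self):
        model = DemographicModel.from_knots(
            [0, 40, 125], [30_000.0, 15_000.0, 20_000.0])
        ld = _exact_ld_data(model)
        op = _TrajectoryOp(model.grid_times, 125, 1250)
        data = _LDData(ld, op)
        theta = model.log_ne.copy()
        f0 = neg_log_pseudo_posterior(theta, data, 1.0, 0.0)
        assert f0 == pytest.approx(0.0, abs=1e-12)
        grad = np.empty_like(theta)
        eps = 1e-6
        for k in range(len(theta)):
            tp, tm = theta.copy(), theta.copy()
            tp[k] += eps
            tm[k] -= eps
            grad[k] = (neg_log_pseudo_posterior(tp, data, 1.0, 0.0)
                       - neg_log_pseudo_posterior(tm, data, 1.0, 0.0)) / (2 * eps)
        assert np.linalg.norm(grad) < 1e-4

    def test_constant_trajectory_has_zero_prior_penalty(self):
        model = scenario("constant").model
        ld = _exact_ld_data(model)
        op = _TrajectoryOp(model.grid_times, 125, 1250)
        data = _LDData(ld, op)
        theta = model.log_ne
        assert neg_log_pseudo_posterior(theta, data, 1.0, 1e9) == \
            pytest.approx(neg_log_pseudo_posterior(theta, data, 1.0, 0.0))

    def test_strong_prior_collapses_to_regularization_null(self, rng):
        """As lambda grows the fit loses all curvature: slopes equalize and,
        through the mild tilt component, shrink toward the best constant."""
        model = scenario("bottleneck").model
        ld = _noisy_ld_data(model, rng, noise=1e-5)
        grid = np.linspace(0.0, 125.0, 9)
        op = _TrajectoryOp(grid, 125, 1250)
        data = _LDData(ld, op)
        from recne.inference import _fit_theta

        theta_inf, _ = _fit_theta(data, 1.0, 1e9, np.full(9, np.log(2e4)), 500)
        slopes = np.diff(theta_inf) / np.diff(grid)
        assert np.max(np.abs(np.diff(slopes))) < 1e-4  # no curvature left
        assert np.max(np.abs(theta_inf - theta_inf.mean())) < 0.02
        # and the level matches the best constant model
        from scipy.optimize import minimize_scalar

        best = minimize_scalar(
            lambda t: float(np.sum(data.nll_terms(np.full(9, t)))),
            bounds=(np.log(1e3), np.log(1e6)), method="bounded")
        assert abs(theta_inf.mean() - best.x) < 0.02

    def test_moderate_prior_tracks_single_exponential_data(self, rng):
        """Data generated from a genuine exponential are followed even under
        strong regularization (the prior taxes it only mildly)."""
        model = DemographicModel.from_knots([0, 125], [5_000.0, 50_000.0])
        ld = _noisy_ld_data(model, rng, noise=1e-5)
        grid = np.linspace(0.0, 125.0, 9)
        op = _TrajectoryOp(grid, 125, 1250)
        data = _LDData(ld, op)
        from recne.inference import _fit_theta

        theta, _ = _fit_theta(data, 1.0, 1000.0, np.full(9, np.log(2e4)), 500)
        fitted = DemographicModel(grid, theta, 125)
        assert rmsle(fitted, model) < 0.35


class _StubData:
    """Minimal residual provider for exercising the power heuristic."""

    def __init__(self, residual_matrix, n_bins):
        self._r = np.asarray(residual_matrix, dtype=float)
        self.n_bins = n_bins

    def residuals(self, theta):
        return self._r


class TestSelectPower:
    def test_independent_bins_give_full_likelihood(self, rng):
        r = rng.standard_normal((10, 64))
        assert select_power(_StubData(r, 64), None) == 1.0

    def test_duplicated_bins_give_half(self, rng):
        base = rng.standard_normal((10, 32))
        r = np.repeat(base, 2, axis=1)  # each bin duplicated
        assert select_power(_StubData(r, 64), None) == pytest.approx(0.5)

    def test_fully_correlated_region_gives_one_over_nbins(self):
        r = np.ones((6, 64))  # zero-variance rows are skipped -> add slope
        r = r * np.ones((6, 1))
        r[:, :] = np.tile(np.full(64, 2.0), (6, 1))
        r += np.arange(6)[:, None] * 0.0
        # constant residual rows carry no autocorrelation information; use
        # slowly varying identical rows instead (correlation 1 at lag 1)
        t = np.linspace(0, 1, 64)
        r = np.tile(t, (6, 1))
        assert select_power(_StubData(r, 64), None) == pytest.approx(1.0 / 64)


class TestDispersion:
    def test_poisson_counts_give_unit_dispersion(self, rng):
        model = scenario("constant").model
        edges = np.arange(2.0, 12.0, 0.5)
        mu = expected_ibd_density(model, edges / 100.0)
        lengths = np.ones(39)
        n_pairs = 200_000
        phis = []
        for _ in range(20):
            counts = rng.poisson(np.outer(lengths, mu) * n_pairs)
            hist = make_hist(counts, lengths, n_pairs)
            phis.append(estimate_dispersion_ibd(hist, model))
        mean_phi = np.mean(phis)
        assert 0.9 < mean_phi < 1.15  # clipped at 1 from below

    def test_overdispersed_counts_detected(self, rng):
        """Negative binomial with variance 2 mu -> phi^2 near 2."""
        model = scenario("constant").model
        edges = np.arange(2.0, 12.0, 0.5)
        mu = expected_ibd_density(model, edges / 100.0)
        lengths = np.ones(39)
        n_pairs = 200_000
        m = np.outer(lengths, mu) * n_pairs
        counts = rng.negative_binomial(n=m, p=0.5)  # mean m, var 2m
        hist = make_hist(counts, lengths, n_pairs)
        phi = estimate_dispersion_ibd(hist, model)
        assert 1.6 < np.median(phi) < 2.5

    def test_single_region_convention(self):
        model = scenario("constant").model
        hist = make_hist(np.array([[5, 3, 1]]), np.ones(1))
        phi = estimate_dispersion_ibd(hist, model)
        np.testing.assert_array_equal(phi, np.ones(3))


class TestFitMap:
    def test_flat_data_stays_near_constant(self, rng):
        """Baseline-only LD: the regularized fit reports an (almost) constant
        trajectory rather than spurious fluctuations."""
        edges = np.arange(0.5, 30.1, 0.5)
        centers = 0.5 * (edges[:-1] + edges[1:])
        b = len(centers)
        n_regions = 15
        from recne.ld import finite_sample_baseline

        base = finite_sample_baseline(200.0, 200.0)
        y = base + rng.normal(0, 2e-5, size=(n_regions, b))
        ld = BinnedLD(np.arange(1, n_regions + 1), edges, y,
                      np.full((n_regions, b), 500, dtype=np.int64),
                      np.full((n_regions, b), 4e-10),
                      np.full((n_regions, b), base), 200.0)
        post = fit_map(ld, FitConfig(seed=0, n_bootstrap=0))
        traj = post.map_model.ne_at(np.arange(1, 126))
        assert traj.max() / traj.min() < 1.5

    def test_monotone_response_to_scaled_signal(self, rng):
        """Uniformly inflating LD above baseline (more sharing) must not
        increase the inferred harmonic-mean size."""
        model = scenario("constant").model
        ld1 = _noisy_ld_data(model, np.random.default_rng(5))
        ld2 = BinnedLD(ld1.regions, ld1.bin_edges,
                       ld1.baseline + 1.6 * (ld1.y - ld1.baseline),
                       ld1.n_pairs, ld1.var, ld1.baseline, ld1.n_haplotypes)
        cfg = FitConfig(seed=0, n_bootstrap=0)
        ne1 = fit_map(ld1, cfg).map_model.ne_at(np.arange(1, 51))
        ne2 = fit_map(ld2, cfg).map_model.ne_at(np.arange(1, 51))
        hmean1 = 1.0 / np.mean(1.0 / ne1)
        hmean2 = 1.0 / np.mean(1.0 / ne2)
        assert hmean2 <= hmean1 * 1.02

    def test_deterministic_given_seed(self, rng):
        model = scenario("collapse").model
        ld = _noisy_ld_data(model, np.random.default_rng(9))
        cfg = FitConfig(seed=3, n_bootstrap=4)
        a = bootstrap_ci(ld, cfg)
        b = bootstrap_ci(ld, cfg)
        np.testing.assert_array_equal(a.map_model.log_ne, b.map_model.log_ne)
        for q in a.quantiles:
            np.testing.assert_array_equal(a.quantiles[q], b.quantiles[q])

    def test_band_ordering(self, rng):
        model = scenario("constant").model
        ld = _noisy_ld_data(model, np.random.default_rng(11))
        post = bootstrap_ci(ld, FitConfig(seed=1, n_bootstrap=8))
        q = post.quantiles
        assert np.all(q["q2.5"] <= q["q25"] + 1e-9)
        assert np.all(q["q25"] <= q["q75"] + 1e-9)
        assert np.all(q["q75"] <= q["q97.5"] + 1e-9)


class TestBootstrapDegenerate:
    def test_identical_regions_zero_width_bands(self):
        model = scenario("constant").model
        ld = _exact_ld_data(model, n_regions=8)
        post = bootstrap_ci(ld, FitConfig(seed=2, n_bootstrap=6))
        width = post.quantiles["q97.5"] - post.quantiles["q2.5"]
        assert np.max(width / post.quantiles["q25"]) < 1e-3

    def test_single_bootstrap_replicate(self, rng):
        model = scenario("constant").model
        ld = _noisy_ld_data(model, np.random.default_rng(21))
        post = bootstrap_ci(ld, FitConfig(seed=4, n_bootstrap=1))
        assert len(post.bootstrap_models) == 1
        rep = post.bootstrap_models[0].ne_at(np.arange(1, 126))
        for q in ("q2.5", "q25", "q75", "q97.5"):
            np.testing.assert_allclose(post.quantiles[q], rep)


class TestModeAgreement:
    @pytest.mark.parametrize("scen_name", ["constant", "collapse"])
    def test_ibd_and_ld_estimates_agree_on_shared_demography(
            self, scen_name, constant_panel, collapse_panel):
        """Both statistics estimate the same target: RMSLE between the two
        MAP trajectories stays small on oracle data from one demography."""
        from recne import bin_ld_curve, filter_ld_regions, simulate_pairwise_ibd
        from recne.simulate import oracle_histogram

        panel, gmap = constant_panel if scen_name == "constant" else collapse_panel
        ld = bin_ld_curve(panel, gmap, seed=0)
        kept, _ = filter_ld_regions(ld)
        cfg = FitConfig(seed=0, n_bootstrap=0)
        post_ld = fit_map(ld.subset(kept), cfg)
        lengths = np.full(12, 0.9)
        segs = simulate_pairwise_ibd(scenario(scen_name), 150_000, lengths,
                                     seed=31)
        hist = oracle_histogram(segs, lengths, 150_000)
        post_ibd = fit_map(hist, cfg)
        assert rmsle(post_ld.map_model, post_ibd.map_model) < 0.35
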