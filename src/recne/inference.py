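"""Regularized power-likelihood inference of N_e(t) from LD or IBD summaries.

The estimator maximizes a pseudo-posterior over piecewise-exponential
trajectories theta = log N_e at the knots of an adaptively chosen time grid:

    objective(theta) = c * sum_{i,b} nll(Y_ib | mu_b(theta))
                       + lambda * sum_k (Delta_k log N_e)^2

* IBD mode: Y_ib are Poisson counts with mean mu_b(theta) L_i n_pairs; the
  negative log-likelihood is the Poisson half-deviance divided by a per-bin
  quasi-likelihood dispersion phi^2_b.
* LD mode: Y_ib are Normal with mean p_b + (1 - p_b) * baseline_ib and the
  empirical within-bin variance.
* The power exponent c in (0, 1] discounts the correlation between bins of
  a region; lambda penalizes changes in the growth rate of log N_e (a
  Gaussian smoothness prior on the trajectory that leaves constant and
  single-exponential histories unpenalized, favoring models with minimal
  population size fluctuations).  Both are tuned automatically by default.

Uncertainty comes from resampling chromosome arms with replacement (the
independence unit), refitting, and reporting per-generation 2.5/25/75/97.5
percentiles (95% and 50% bands).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .demography import DemographicModel, adapt_time_grid
from .expectations import SampleAgeTable, pair_age_density
from .ibd import IBDHistogram
from .ld import BinnedLD

logger = logging.getLogger("recne")

LOG_NE_BOUNDS = (np.log(10.0), np.log(1e8))


@dataclass
class FitConfig:
    """Hyperparameters of the trajectory fit.

    ``power`` (the likelihood exponent c) and ``prior_strength`` (lambda)
    accept "auto"; c is then tuned from the residual bin-autocorrelation of a
    pilot fit and lambda by leave-regions-out cross-validation.
    """

    t_max: int = 125
    n_time_intervals: int = 16
    power: float | str = "auto"
    prior_strength: float | str = "auto"
    n_bootstrap: int = 100
    seed: int = 0
    horizon: int | None = None
    maxiter: int = 300
    lambda_grid: tuple = (0.1, 1.0, 10.0, 100.0, 1000.0)
    cv_folds: int = 3

    def __post_init__(self):
        if isinstance(self.power, (int, float)) and not 0 < self.power <= 1:
            raise ValueError("power exponent c must be in (0, 1]")
        if self.n_bootstrap < 0:
            raise ValueError("n_bootstrap must be >= 0")
        if self.horizon is None:
            self.horizon = 10 * self.t_max


@dataclass
class NePosterior:
    """MAP trajectory with bootstrap quantile bands.

    ``quantiles`` maps band labels ("q2.5", "q25", "q75", "q97.5") to
    per-generation values at generations 1..t_max.
    """

    map_model: DemographicModel
    bootstrap_models: list = field(default_factory=list)
    quantiles: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)

    def trajectory(self) -> pd.DataFrame:
        gens = np.arange(1, self.map_model.t_max + 1)
        df = pd.DataFrame({"generation": gens, "Ne_map": self.map_model.ne_at(gens)})
        for label, vals in self.quantiles.items():
            df[label] = vals
        return df

    def to_tsv(self, path) -> None:
        self.trajectory().to_csv(path, sep="\t", index=False, float_format="%.4f")

    def diagnostics_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.diagnostics, fh, indent=2, default=_jsonable)


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    return str(x)


# ------------------------------------------------------------ observation ops
class _TrajectoryOp:
    """Maps theta (log N_e at grid knots) to q(g)-derived expectations.

    The genetic-distance decay matrices depend only on the bin layout and the
    horizon, so they are precomputed once; each objective evaluation costs a
    hazard cumsum plus a matrix-vector product.
    """

    def __init__(self, grid_times: np.ndarray, t_max: int, horizon: int,
                 max_age: int = 0):
        self.grid_times = grid_times
        self.t_max = t_max
        self.horizon = horizon
        self.total = horizon + max_age
        t = np.arange(1, self.total + 1, dtype=float)
        self.t_clipped = np.minimum(t, t_max)

    def ne_per_generation(self, theta: np.ndarray) -> np.ndarray:
        return np.exp(np.interp(self.t_clipped, self.grid_times, theta))

    def hazard_survival(self, theta: np.ndarray):
        ne = self.ne_per_generation(theta)
        h = 1.0 / ne
        log_s = np.concatenate([[0.0], np.cumsum(np.log1p(-h))])
        return h, log_s, ne


class _IBDData:
    """Precomputed Poisson-mean operator and flattened observations."""

    def __init__(self, hist: IBDHistogram, op: _TrajectoryOp):
        self.hist = hist
        self.op = op
        g = np.arange(1, op.total + 1, dtype=float)
        edges = hist.bin_edges_morgans
        decay = np.exp(-2.0 * np.outer(g, edges))
        self.M = (2.0 * g)[:, None] * (decay[:, :-1] - decay[:, 1:])
        self.exposure = hist.lengths_morgans[:, None] * hist.n_pairs  # (R, 1)
        self.phi2 = hist.dispersion.copy()

    @property
    def n_bins(self) -> int:
        return self.hist.n_bins

    def mu_bins(self, theta: np.ndarray) -> np.ndarray:
        h, log_s, _ = self.op.hazard_survival(theta)
        q = h * np.exp(log_s[:-1])
        return q @ self.M

    def nll_terms(self, theta: np.ndarray) -> np.ndarray:
        """Quasi-Poisson half-deviance per (region, bin)."""
        mu = np.maximum(self.mu_bins(theta)[None, :] * self.exposure, 1e-300)
        y = self.hist.counts.astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            logterm = np.where(y > 0, y * np.log(y / mu), 0.0)
        return (logterm - (y - mu)) / self.phi2[None, :]

    def residuals(self, theta: np.ndarray) -> np.ndarray:
        """Signed deviance residuals (region x bin)."""
        mu = np.maximum(self.mu_bins(theta)[None, :] * self.exposure, 1e-300)
        y = self.hist.counts.astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            logterm = np.where(y > 0, y * np.log(y / mu), 0.0)
        d2 = np.maximum(2.0 * (logterm - (y - mu)), 0.0)
        return np.sign(y - mu) * np.sqrt(d2 / self.phi2[None, :])

    def subset(self, region_ids) -> "_IBDData":
        return _IBDData(self.hist.subset(region_ids), self.op)

    def moment_guess(self) -> float:
        total = self.hist.counts.sum()
        grid = np.exp(np.linspace(np.log(50.0), np.log(1e7), 40))
        totals = []
        for n in grid:
            theta = np.full(len(self.op.grid_times), np.log(n))
            totals.append(float(np.sum(self.mu_bins(theta)[None, :] * self.exposure)))
        totals = np.array(totals)
        if total <= totals[-1]:
            return float(grid[-1])
        if total >= totals[0]:
            return float(grid[0])
        # totals decrease with N
        return float(np.exp(np.interp(-np.log(max(total, 1e-12)),
                                      -np.log(totals), np.log(grid))))


class _LDData:
    """Precomputed p_IBD operator (optionally age-marginalized) and
    flattened Normal observations."""

    def __init__(self, ld: BinnedLD, op: _TrajectoryOp,
                 ages: SampleAgeTable | None = None):
        self.ld = ld
        self.op = op
        u = ld.bin_centers_cm / 100.0
        self.u = u
        dt = np.arange(1, op.horizon + 1, dtype=float)
        base_decay = np.exp(-2.0 * np.outer(dt, u))  # (H, B)
        if ages is None or ages.is_modern():
            self.age_groups = [(0, 1.0, np.ones_like(u))]
        else:
            dens = pair_age_density(ages)
            self.age_groups = []
            for a in np.unique(dens.a_old):
                sel = dens.a_old == a
                w_a = float(dens.weight[sel].sum())
                gap_factor = (dens.weight[sel] / w_a) @ np.exp(
                    -np.outer(dens.gap[sel].astype(float), u))
                self.age_groups.append((int(a), w_a, gap_factor))
        self.base_decay = base_decay
        self.y = ld.y
        self.baseline = ld.baseline
        self.lik_var = self._likelihood_variance(ld)
        self.mask = ~np.isnan(ld.y) & np.isfinite(self.lik_var) & (self.lik_var > 0)

    @staticmethod
    def _likelihood_variance(ld: BinnedLD) -> np.ndarray:
        """Per-bin observation variance for the Normal likelihood.

        The cross-region spread of Y_{i,b} is the usual variance estimator
        for the per-bin observation noise (and absorbs overdispersion);
        regions are rescaled by their relative pair counts.  Pair-level
        within-bin variances are too unstable when a bin holds few, mutually
        correlated pairs, so they are used only when fewer than 3 regions
        are available.
        """
        if ld.y.shape[0] < 3:
            return ld.var.copy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            s2 = np.nanvar(ld.y, axis=0, ddof=1)
            npair = ld.n_pairs.astype(float)
            npair[npair == 0] = np.nan
            rel = npair / np.nanmean(npair, axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = s2[None, :] / rel
        # degenerate bins (identical regions up to rounding noise) fall back
        # to pair-level variances
        tiny = (1e-9 * np.nanmax(np.abs(ld.y))) ** 2 if np.isfinite(ld.y).any() else 0.0
        bad = ~np.isfinite(out) | (out <= tiny)
        out[bad] = ld.var[bad]
        pos = out[np.isfinite(out) & (out > 0)]
        floor = 1e-4 * np.median(pos) if pos.size else 1e-16
        out[~np.isfinite(out) | (out <= 0)] = floor
        return np.maximum(out, floor)

    @property
    def n_bins(self) -> int:
        return self.ld.n_bins

    def p_ibd(self, theta: np.ndarray) -> np.ndarray:
        h, log_s, ne = self.op.hazard_survival(theta)
        H = self.op.horizon
        x = np.exp(-2.0 * self.u)
        out = np.zeros_like(self.u)
        for a, w_a, gap_factor in self.age_groups:
            qa = h[a:a + H] * np.exp(log_s[a:a + H] - log_s[a])
            p_a = qa @ self.base_decay
            tail_mass = np.exp(log_s[a + H] - log_s[a])
            n_last = ne[min(a + H, len(ne)) - 1]
            p_a += tail_mass * np.exp(-2.0 * H * self.u) * (x / n_last) / (
                1.0 - (1.0 - 1.0 / n_last) * x)
            out += w_a * p_a * gap_factor
        return out

    def mu(self, theta: np.ndarray) -> np.ndarray:
        p = self.p_ibd(theta)
        return p[None, :] + (1.0 - p[None, :]) * self.baseline

    def nll_terms(self, theta: np.ndarray) -> np.ndarray:
        mu = self.mu(theta)
        out = np.zeros_like(self.y)
        out[self.mask] = 0.5 * (self.y[self.mask] - mu[self.mask]) ** 2 / self.lik_var[self.mask]
        return out

    def residuals(self, theta: np.ndarray) -> np.ndarray:
        mu = self.mu(theta)
        r = np.full(self.y.shape, np.nan)
        r[self.mask] = (self.y[self.mask] - mu[self.mask]) / np.sqrt(self.lik_var[self.mask])
        return r

    def subset(self, region_ids) -> "_LDData":
        # likelihood variances stay frozen at the full-data estimates
        pos = {r: i for i, r in enumerate(self.ld.regions)}
        idx = np.array([pos[r] for r in region_ids], dtype=int)
        new = _LDData.__new__(_LDData)
        new.ld = self.ld.subset(region_ids)
        new.op = self.op
        new.u = self.u
        new.age_groups = self.age_groups
        new.base_decay = self.base_decay
        new.y = new.ld.y
        new.baseline = new.ld.baseline
        new.lik_var = self.lik_var[idx]
        new.mask = ~np.isnan(new.y) & np.isfinite(new.lik_var) & (new.lik_var > 0)
        return new

    def moment_guess(self) -> float:
        short = self.u <= 0.05
        estimates = []
        for b in np.where(short)[0]:
            ok = self.mask[:, b]
            if ok.sum() == 0:
                continue
            ybar = float(np.mean(self.y[ok, b]))
            base = float(np.mean(self.baseline[ok, b]))
            p_hat = (ybar - base) / max(1.0 - base, 1e-9)
            if p_hat > 1e-8:
                estimates.append((1.0 / p_hat - 1.0) / (2.0 * self.u[b]))
        if not estimates:
            return 1e6  # no signal above baseline: weakly informative large size
        return float(np.clip(np.median(estimates), 50.0, 1e7))


def _make_data(data, op, ages):
    if isinstance(data, IBDHistogram):
        return _IBDData(data, op)
    if isinstance(data, BinnedLD):
        return _LDData(data, op, ages)
    raise TypeError("data must be an IBDHistogram or BinnedLD")


# ----------------------------------------------------------------- objective
#: Relative weight of the growth-rate (slope) component of the prior.  The
#: curvature component suppresses oscillations but leaves a global
#: exponential tilt completely free; the mild slope component shrinks tilts
#: that are not supported by the data (for which cross-validation keeps
#: lambda small) without forbidding genuine expansions or collapses.
SLOPE_PENALTY_WEIGHT = 0.1


def _fluctuation_penalty(theta: np.ndarray, grid_times: np.ndarray) -> float:
    """Fluctuation prior on the trajectory: squared changes of the growth
    rate of log N_e, plus a mildly weighted squared growth rate itself.

    Slopes are taken per grid interval and rescaled by the mean interval
    width, so the penalty is invariant to grid refinement.  A constant
    history costs nothing; a single exponential costs only the small slope
    component; oscillations cost full curvature terms.
    """
    widths = np.diff(grid_times)
    slopes = np.diff(theta) / widths
    scale = float(np.mean(widths))
    curv = float(np.sum((np.diff(slopes) * scale) ** 2))
    tilt = float(np.sum((slopes * scale) ** 2))
    return curv + SLOPE_PENALTY_WEIGHT * tilt


def neg_log_pseudo_posterior(theta, data_op, c: float, lam: float) -> float:
    """c * sum nll(Y | mu(theta)) + lambda * fluctuation penalty."""
    theta = np.asarray(theta, float)
    nll = float(np.sum(data_op.nll_terms(theta)))
    penalty = _fluctuation_penalty(theta, data_op.op.grid_times)
    out = c * nll + lam * penalty
    if not np.isfinite(out):
        terms = data_op.nll_terms(np.asarray(theta, float))
        bad = np.argwhere(~np.isfinite(terms))
        raise FloatingPointError(f"non-finite objective; offending bins {bad[:3]}")
    return out


def _minimize(fun, x0, bounds, maxiter):
    res = optimize.minimize(fun, x0, method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": maxiter})
    return res


def _fit_theta(data_op, c, lam, x0, maxiter):
    k = len(x0)
    bounds = [LOG_NE_BOUNDS] * k
    res = _minimize(lambda th: neg_log_pseudo_posterior(th, data_op, c, lam),
                    x0, bounds, maxiter)
    return res.x, res


def _single_exponential_fit(data_op, c, grid_times, maxiter):
    """Best 2-parameter (endpoint) exponential trajectory, no prior."""
    t_frac = (grid_times - grid_times[0]) / (grid_times[-1] - grid_times[0])

    def expand(x2):
        return x2[0] + (x2[1] - x2[0]) * t_frac

    def fun(x2):
        return neg_log_pseudo_posterior(expand(x2), data_op, c, 0.0)

    guess = np.log(data_op.moment_guess())
    res = _minimize(fun, np.array([guess, guess]), [LOG_NE_BOUNDS] * 2, maxiter)
    return expand(res.x)


# ------------------------------------------------------------- hyperparameters
def select_power(data_op, theta_pilot, n_bins_total: int | None = None) -> float:
    """Power exponent c from residual bin-autocorrelation under a pilot fit.

    The effective number of independent bins per region is estimated from the
    mean absolute lag-1 autocorrelation r of the residual sequences:
    ESS_ratio = 1 / (1 - r), and c = 1/ESS_ratio = 1 - r, snapped to the
    grid {1, 1/2, 1/4, ..., 1/n_bins}.
    """
    res = data_op.residuals(theta_pilot)
    acs = []
    for i in range(res.shape[0]):
        r = res[i][~np.isnan(res[i])]
        if len(r) < 4 or np.std(r) == 0:
            continue
        ac = np.corrcoef(r[:-1], r[1:])[0, 1]
        if np.isfinite(ac):
            acs.append(abs(ac))
    n_bins = n_bins_total or data_op.n_bins
    grid = [1.0]
    while grid[-1] / 2 > 1.0 / n_bins:
        grid.append(grid[-1] / 2)
    grid.append(1.0 / n_bins)
    grid = np.array(grid)
    if not acs:
        return 1.0
    c_raw = max(1.0 / n_bins, 1.0 - float(np.mean(acs)))
    return float(grid[np.argmin(np.abs(np.log(grid) - np.log(c_raw)))])


def select_prior_strength(data_op, c: float, x0, config: FitConfig,
                          rng: np.random.Generator) -> float:
    """lambda by leave-regions-out predictive score over a 10^k grid.

    The strongest lambda whose mean held-out score is within one standard
    error of the best is chosen (the usual one-SE rule): when the data carry
    little signal the fit is pushed toward trajectories without spurious
    fluctuations rather than toward the noise-level CV minimum.
    """
    regions = list(data_op.ld.regions if isinstance(data_op, _LDData)
                   else data_op.hist.regions)
    if len(regions) < 2 * config.cv_folds:
        return float(config.lambda_grid[len(config.lambda_grid) // 2])
    perm = rng.permutation(len(regions))
    folds = np.array_split(perm, config.cv_folds)
    fold_scores = np.zeros((len(config.lambda_grid), len(folds)))
    for li, lam in enumerate(config.lambda_grid):
        for fi, fold in enumerate(folds):
            test_ids = [regions[i] for i in fold]
            train_ids = [r for r in regions if r not in set(test_ids)]
            train = data_op.subset(train_ids)
            # warm-started ranking fits need far fewer iterations
            theta, _ = _fit_theta(train, c, lam, x0, max(40, config.maxiter // 4))
            test = data_op.subset(test_ids)
            fold_scores[li, fi] = float(np.sum(test.nll_terms(theta)))
    mean = fold_scores.mean(axis=1)
    best = int(np.argmin(mean))
    se = fold_scores[best].std(ddof=1) / np.sqrt(len(folds))
    eligible = np.where(mean <= mean[best] + se)[0]
    return float(config.lambda_grid[int(eligible.max())])


def estimate_dispersion_ibd(hist: IBDHistogram, model: DemographicModel,
                            horizon: int | None = None) -> np.ndarray:
    """Per-bin quasi-likelihood dispersion phi^2_b.

    Pearson X^2 across regions in each bin under means mu_b L_i n_pairs,
    divided by (n_regions - 1) and clipped below at 1.  A single region
    gives phi^2 = 1 by convention.
    """
    if horizon is None:
        horizon = 10 * model.t_max
    op = _TrajectoryOp(model.grid_times, model.t_max, horizon)
    data = _IBDData(hist, op)
    mu = np.maximum(data.mu_bins(model.log_ne)[None, :] * data.exposure, 1e-300)
    n_regions = hist.counts.shape[0]
    if n_regions < 2:
        return np.ones(hist.n_bins)
    x2 = np.sum((hist.counts - mu) ** 2 / mu, axis=0)
    return np.maximum(1.0, x2 / (n_regions - 1))


# ------------------------------------------------------------------- fitting
def fit_map(data, config: FitConfig | None = None,
            ages: SampleAgeTable | None = None) -> NePosterior:
    """MAP trajectory fit with automatic c/lambda tuning and one adaptive
    re-gridding round-trip.  Deterministic given the config seed."""
    config = config or FitConfig()
    rng = np.random.default_rng(config.seed)
    horizon = config.horizon
    max_age = 0
    if ages is not None and not ages.is_modern():
        max_age = int(np.ceil(ages.ages["age_hi"].max()))

    def build(grid_times):
        op = _TrajectoryOp(grid_times, config.t_max, horizon, max_age)
        return _make_data(data, op, ages)

    # initial grid from a constant pilot model at the moment-based guess
    op0 = _TrajectoryOp(np.array([0.0, float(config.t_max)]), config.t_max,
                        horizon, max_age)
    guess = _make_data(data, op0, ages).moment_guess()
    pilot_const = DemographicModel.constant(guess, config.t_max)
    grid = adapt_time_grid(pilot_const, config.n_time_intervals).grid_times
    data_op = build(grid)

    # pilot fit: multi-start from the constant guess and the best single
    # exponential, c = 1, moderate prior
    lam_pilot = 1.0
    x_const = np.full(len(grid), np.log(guess))
    x_exp = _single_exponential_fit(data_op, 1.0, grid, config.maxiter)
    starts = [x_const, x_exp]
    best = None
    for x0 in starts:
        theta, res = _fit_theta(data_op, 1.0, lam_pilot, x0, config.maxiter)
        if best is None or res.fun < best[1].fun:
            best = (theta, res)
    theta_pilot = best[0]

    if isinstance(data, IBDHistogram):
        # update quasi-likelihood dispersions from the pilot, then refit
        pilot_model = DemographicModel(grid, theta_pilot, config.t_max)
        data.dispersion = estimate_dispersion_ibd(data, pilot_model, horizon)
        data_op = build(grid)
        theta_pilot, _ = _fit_theta(data_op, 1.0, lam_pilot, theta_pilot,
                                    config.maxiter)

    c = (select_power(data_op, theta_pilot) if config.power == "auto"
         else float(config.power))
    lam = (select_prior_strength(data_op, c, theta_pilot, config, rng)
           if config.prior_strength == "auto" else float(config.prior_strength))

    theta1, res1 = _fit_theta(data_op, c, lam, theta_pilot, config.maxiter)
    # with the tuned prior a constant start may win on weak data
    theta1b, res1b = _fit_theta(data_op, c, lam, x_const, config.maxiter)
    if res1b.fun < res1.fun:
        theta1, res1 = theta1b, res1b
    # one adaptive re-gridding round-trip
    model1 = DemographicModel(grid, theta1, config.t_max)
    grid2 = adapt_time_grid(model1, config.n_time_intervals).grid_times
    data_op2 = build(grid2)
    x0_2 = np.interp(grid2, grid, theta1)
    theta2, res2 = _fit_theta(data_op2, c, lam, x0_2, config.maxiter)
    if res2.fun <= res1.fun:
        final_grid, theta_final, res = grid2, theta2, res2
    else:
        final_grid, theta_final, res = grid, theta1, res1
    converged = bool(res.success)
    if not converged:
        warnings.warn("optimizer did not report convergence; returning best "
                      "trajectory found")
    map_model = DemographicModel(final_grid, theta_final, config.t_max)
    diagnostics = {
        "c": c, "lambda": lam, "objective": float(res.fun),
        "converged": converged, "n_regions": _n_regions(data),
        "grid_times": final_grid, "moment_guess": guess,
        "mode": "ibd" if isinstance(data, IBDHistogram) else "ld",
    }
    logger.info("MAP fit: c=%.4g lambda=%.4g objective=%.6g converged=%s",
                c, lam, res.fun, converged)
    post = NePosterior(map_model, diagnostics=diagnostics)
    post._fit_state = (final_grid, c, lam, ages, horizon, max_age)  # for bootstrap
    return post


def _n_regions(data) -> int:
    return len(data.regions if isinstance(data, IBDHistogram) else data.regions)


def bootstrap_ci(data, config: FitConfig, ages: SampleAgeTable | None = None,
                 map_result: NePosterior | None = None) -> NePosterior:
    """Chromosome-arm bootstrap confidence bands.

    Time grid, c and lambda stay frozen at the point fit; each replicate
    resamples the kept regions with replacement, refits from the MAP start,
    and per-generation 2.5/25/75/97.5 percentiles are reported.
    """
    config = config or FitConfig()
    if map_result is None:
        map_result = fit_map(data, config, ages)
    grid, c, lam, ages, horizon, max_age = map_result._fit_state
    op = _TrajectoryOp(grid, config.t_max, horizon, max_age)
    data_op = _make_data(data, op, ages)
    theta_map = np.interp(grid, map_result.map_model.grid_times,
                          map_result.map_model.log_ne)
    regions = np.asarray(data.regions)
    rng = np.random.default_rng(config.seed + 1)
    gens = np.arange(1, config.t_max + 1)
    trajs, failures = [], 0
    models = []
    for _ in range(config.n_bootstrap):
        ids = regions[rng.integers(0, len(regions), size=len(regions))]
        try:
            rep = data_op.subset(ids)
            theta, _ = _fit_theta(rep, c, lam, theta_map, config.maxiter)
            m = DemographicModel(grid, theta, config.t_max)
            models.append(m)
            trajs.append(m.ne_at(gens))
        except Exception:  # pragma: no cover - tolerated replicate failure
            failures += 1
    if config.n_bootstrap and failures > 0.1 * config.n_bootstrap:
        warnings.warn(f"{failures}/{config.n_bootstrap} bootstrap replicates failed")
    quantiles = {}
    if trajs:
        arr = np.array(trajs)
        for q, label in ((2.5, "q2.5"), (25, "q25"), (75, "q75"), (97.5, "q97.5")):
            quantiles[label] = np.percentile(arr, q, axis=0)
    diag = dict(map_result.diagnostics)
    diag.update({"n_bootstrap": config.n_bootstrap, "bootstrap_failures": failures})
    post = NePosterior(map_result.map_model, models, quantiles, diag)
    post._fit_state = map_result._fit_state
    return post
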