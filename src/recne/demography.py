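"""Piecewise-exponential effective-size trajectories and pair-coalescence distributions.

The inference target throughout the package is the haploid effective
population size :math:`N_e(t)`, parameterized as a piecewise-exponential
function of time ``t`` in generations before present: ``log N_e`` is linear
between knots of a strictly increasing time grid starting at 0 and ending at
``t_max`` (default 125), and :math:`N_e` is held constant beyond ``t_max``.
Diploid census size corresponds to roughly ``N_e / 2``.

A discrete-generation pair coalescent is used everywhere: two haploid
lineages coalesce at generation ``g`` with probability
``q(g) = (1/N_e(g)) * prod_{u<g} (1 - 1/N_e(u))``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

DEFAULT_T_MAX = 125
#: Truncation horizon of the discrete pair coalescent, in generations.
DEFAULT_HORIZON_FACTOR = 10
#: Minimum observable IBD segment length (Morgans) used by the
#: equal-ancestor time-grid weight.
U_MIN_MORGANS = 0.02


@dataclass(frozen=True)
class DemographicModel:
    """Haploid effective size trajectory, exponential between grid knots.

    Parameters
    ----------
    grid_times
        Strictly increasing generation times; first entry 0, last ``t_max``.
    log_ne
        Natural log of the haploid effective size at each grid time.
    """

    grid_times: np.ndarray
    log_ne: np.ndarray
    t_max: int = DEFAULT_T_MAX

    def __post_init__(self):
        gt = np.asarray(self.grid_times, dtype=float)
        ln = np.asarray(self.log_ne, dtype=float)
        if gt.ndim != 1 or ln.shape != gt.shape:
            raise ValueError("grid_times and log_ne must be 1-d arrays of equal length")
        if gt[0] != 0 or not np.all(np.diff(gt) > 0):
            raise ValueError("grid_times must start at 0 and be strictly increasing")
        if abs(gt[-1] - self.t_max) > 1e-9:
            raise ValueError(f"last grid time must equal t_max={self.t_max}")
        if not np.all(np.isfinite(ln)):
            raise ValueError("log_ne must be finite")
        object.__setattr__(self, "grid_times", gt)
        object.__setattr__(self, "log_ne", ln)

    @classmethod
    def constant(cls, ne: float, t_max: int = DEFAULT_T_MAX) -> "DemographicModel":
        return cls(np.array([0.0, float(t_max)]), np.log([ne, ne]), t_max)

    @classmethod
    def from_knots(cls, times, ne_values, t_max: int = DEFAULT_T_MAX) -> "DemographicModel":
        """Build from (time, Ne) knots; endpoints 0 / t_max added by constant
        extension if missing."""
        times = np.asarray(times, dtype=float)
        ne_values = np.asarray(ne_values, dtype=float)
        order = np.argsort(times)
        times, ne_values = times[order], ne_values[order]
        if times[0] > 0:
            times = np.r_[0.0, times]
            ne_values = np.r_[ne_values[0], ne_values]
        if times[-1] < t_max:
            times = np.r_[times, float(t_max)]
            ne_values = np.r_[ne_values, ne_values[-1]]
        elif times[-1] > t_max:
            raise ValueError("knot beyond t_max")
        return cls(times, np.log(ne_values), t_max)

    def ne_at(self, t) -> np.ndarray | float:
        """Haploid effective size at time(s) ``t`` (generations >= 0).

        Log-linear interpolation within the grid; constant beyond ``t_max``.
        """
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr < 0):
            raise ValueError("t must be >= 0")
        out = np.exp(np.interp(np.minimum(t_arr, self.t_max), self.grid_times, self.log_ne))
        return out if t_arr.ndim else float(out)

    def ne_trajectory(self, horizon: int) -> np.ndarray:
        """N_e at integer generations 1..horizon (constant past t_max)."""
        return self.ne_at(np.arange(1, horizon + 1))

    def with_log_ne(self, log_ne) -> "DemographicModel":
        return DemographicModel(self.grid_times.copy(), np.asarray(log_ne, float), self.t_max)

    def regrid(self, new_times) -> "DemographicModel":
        """Re-interpolate the trajectory onto a new grid (same t_max)."""
        new_times = np.asarray(new_times, dtype=float)
        log_new = np.interp(new_times, self.grid_times, self.log_ne)
        return DemographicModel(new_times, log_new, self.t_max)

    def to_tsv(self, path) -> None:
        """Write the trajectory at integer generations as two-column TSV."""
        gens = np.arange(0, self.t_max + 1)
        ne = self.ne_at(gens)
        with open(path, "w") as fh:
            fh.write("generation\tNe\n")
            for g, n in zip(gens, ne):
                fh.write(f"{g}\t{n:.6f}\n")


@dataclass(frozen=True)
class CoalescentDistribution:
    """Distribution of the pair coalescence generation, truncated at a horizon.

    ``pmf[g-1]`` is the probability that a random pair of haploid lineages
    coalesces exactly at generation ``g``; ``tail_mass`` is the probability of
    coalescing beyond the horizon.
    """

    times: np.ndarray
    pmf: np.ndarray
    tail_mass: float
    #: N_e at the horizon, used to continue the hazard analytically.
    ne_tail: float = field(default=np.nan)

    @property
    def horizon(self) -> int:
        return int(self.times[-1])


def coalescent_pmf(model: DemographicModel, horizon: int | None = None) -> CoalescentDistribution:
    """Discrete-generation pair coalescence pmf under ``model``.

    q(g) = (1/N_e(g)) * prod_{u=1}^{g-1} (1 - 1/N_e(u)), g = 1..horizon,
    with the residual mass prod_{u=1}^{horizon} (1 - 1/N_e(u)) reported as
    ``tail_mass``.
    """
    if horizon is None:
        horizon = DEFAULT_HORIZON_FACTOR * model.t_max
    if horizon < model.t_max:
        raise ValueError("horizon must be >= t_max")
    ne = model.ne_trajectory(horizon)
    if np.any(ne <= 1.0):
        raise ValueError("invalid model: N_e(t) <= 1")
    hazard = 1.0 / ne
    log_surv = np.concatenate([[0.0], np.cumsum(np.log1p(-hazard))])
    pmf = hazard * np.exp(log_surv[:-1])
    tail = float(np.exp(log_surv[-1]))
    return CoalescentDistribution(np.arange(1, horizon + 1), pmf, tail, ne_tail=float(ne[-1]))


def _segment_weight(model: DemographicModel, horizon: int | None = None,
                    u_min: float = U_MIN_MORGANS) -> tuple[np.ndarray, np.ndarray]:
    """Per-generation weight of observable-IBD-segment ancestors.

    w(g) = q(g) * 2g * exp(-2 g u_min): the expected density (per Morgan, per
    pair) of segments longer than ``u_min`` left by ancestors at generation g.
    """
    coal = coalescent_pmf(model, horizon)
    g = coal.times.astype(float)
    w = coal.pmf * 2.0 * g * np.exp(-2.0 * g * u_min)
    return coal.times, w


def adapt_time_grid(model: DemographicModel, n_intervals: int,
                    u_min: float = U_MIN_MORGANS) -> DemographicModel:
    """Re-knot the grid so each interval holds equal observable-ancestor mass.

    Intervals of ``(0, t_max]`` are placed at the quantiles of the weight
    w(g) = q(g) * 2g * exp(-2 g u_min) restricted to g <= t_max; the input
    trajectory is re-interpolated onto the new knots.  Degenerate weight
    (mass concentrated in a single generation) falls back to a uniform grid.
    """
    if n_intervals < 1:
        raise ValueError("n_intervals must be >= 1")
    if n_intervals == 1:
        return model.regrid(np.array([0.0, float(model.t_max)]))
    times, w = _segment_weight(model, horizon=model.t_max, u_min=u_min)
    total = w.sum()
    if total <= 0 or np.count_nonzero(w) < 2:
        warnings.warn("degenerate ancestor-weight mass; falling back to uniform time grid")
        knots = np.linspace(0.0, model.t_max, n_intervals + 1)
        return model.regrid(knots)
    cdf = np.cumsum(w) / total
    probs = np.arange(1, n_intervals) / n_intervals
    # inverse cdf over integer generations, interpolated for sub-generation knots
    inner = np.interp(probs, cdf, times.astype(float))
    knots = np.concatenate([[0.0], inner, [float(model.t_max)]])
    knots = _enforce_strict(knots, model.t_max)
    return model.regrid(knots)


def _enforce_strict(knots: np.ndarray, t_max: float, min_gap: float = 0.5) -> np.ndarray:
    """Nudge knots to be strictly increasing with a minimum spacing."""
    out = knots.copy()
    for i in range(1, len(out)):
        if out[i] - out[i - 1] < min_gap:
            out[i] = out[i - 1] + min_gap
    if out[-1] > t_max:
        # squeeze back into range from the right
        out = np.minimum(out, t_max)
        for i in range(len(out) - 2, 0, -1):
            if out[i + 1] - out[i] < min_gap:
                out[i] = out[i + 1] - min_gap
        out[0] = 0.0
    return out


def rmsle(estimate: DemographicModel, truth: DemographicModel,
          t_range: tuple[int, int] = (1, 50)) -> float:
    """Root mean squared log-error between two trajectories.

    sqrt(mean over integer generations of (log N_e_hat(t) - log N_e(t))^2),
    natural logs, default range 1..50.
    """
    lo, hi = t_range
    gens = np.arange(lo, hi + 1)
    diff = np.log(estimate.ne_at(gens)) - np.log(truth.ne_at(gens))
    return float(np.sqrt(np.mean(diff ** 2)))
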