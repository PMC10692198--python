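"""Expected IBD segment counts and LD levels under a demographic model.

Under the sequentially Markovian approximation, conditional on a pair of
haploid lineages coalescing ``g`` generations ago, IBD-segment boundaries
occur along the genome at rate ``2g`` per Morgan (the pair is separated by
``2g`` meioses) and segment lengths are Exp(2g).  Hence:

* expected segments per pair per Morgan with length in ``[u_lo, u_hi)``:
  ``mu_b = sum_g q(g) * 2g * (exp(-2 g u_lo) - exp(-2 g u_hi))``;
* probability that a random haplotype pair is unbroken by recombination
  across a distance ``u``: ``p_IBD(u) = sum_g q(g) * exp(-2 g u)``,

with ``q(g)`` the discrete pair-coalescence pmf.  Long-range LD is driven by
such unbroken sharing, so the expected mean R^2 at distance ``u`` is
``p_IBD(u) + (1 - p_IBD(u)) * beta(n)`` with ``beta`` the finite-sample
baseline of the R^2 estimator under independence.

For heterogeneous sampling times the coalescence clock starts at the age of
the older sample ``a`` and the pair is separated by ``2t - 2a + gap``
meioses, so the exponent generalizes accordingly and the pair-age density is
marginalized out.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .demography import DemographicModel, coalescent_pmf
from .ld import finite_sample_baseline

DEFAULT_GENERATION_YEARS = 29.0


# ----------------------------------------------------------------- ages
@dataclass
class SampleAgeTable:
    """Per-sample age interval [lo, hi] in generations before reference time."""

    ages: pd.DataFrame  # sample_id, age_lo, age_hi

    def __post_init__(self):
        a = self.ages
        if not {"sample_id", "age_lo", "age_hi"}.issubset(a.columns):
            raise ValueError("age table needs sample_id, age_lo, age_hi")
        if (a["age_lo"] < 0).any() or (a["age_lo"] > a["age_hi"]).any():
            raise ValueError("require 0 <= age_lo <= age_hi")
        if not np.all(np.isfinite(a[["age_lo", "age_hi"]].to_numpy())):
            raise ValueError("age intervals must be finite")

    @classmethod
    def zeros(cls, sample_ids) -> "SampleAgeTable":
        return cls(pd.DataFrame({"sample_id": list(sample_ids),
                                 "age_lo": 0, "age_hi": 0}))

    @classmethod
    def from_tsv(cls, path) -> "SampleAgeTable":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        self.ages.to_csv(path, sep="\t", index=False)

    @property
    def n_samples(self) -> int:
        return len(self.ages)

    def is_modern(self) -> bool:
        return bool((self.ages[["age_lo", "age_hi"]].to_numpy() == 0).all())


def years_to_generations(years, generation_years: float = DEFAULT_GENERATION_YEARS):
    """Convert an age in years before present to generations."""
    return np.asarray(years, dtype=float) / generation_years


@dataclass
class PairAgeDensity:
    """Discrete density of (age of older sample, age gap) over random pairs."""

    a_old: np.ndarray
    gap: np.ndarray
    weight: np.ndarray

    def __post_init__(self):
        if np.any(self.weight < 0) or abs(self.weight.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be nonnegative and sum to 1")


def pair_age_density(ages: SampleAgeTable) -> PairAgeDensity:
    """Density of (a_old, gap) for a uniformly chosen pair of samples,
    each sample's age uniform over the integer generations of its interval."""
    lo = ages.ages["age_lo"].to_numpy().round().astype(int)
    hi = ages.ages["age_hi"].to_numpy().round().astype(int)
    n = len(lo)
    if n < 2:
        raise ValueError("need >= 2 samples")
    acc: dict[tuple[int, int], float] = {}
    n_pairs = n * (n - 1) / 2
    for i in range(n):
        ai = np.arange(lo[i], hi[i] + 1)
        wi = 1.0 / len(ai)
        for j in range(i + 1, n):
            aj = np.arange(lo[j], hi[j] + 1)
            wj = 1.0 / len(aj)
            A = np.maximum(ai[:, None], aj[None, :])
            D = np.abs(ai[:, None] - aj[None, :])
            w = wi * wj / n_pairs
            for a, d in zip(A.ravel(), D.ravel()):
                acc[(int(a), int(d))] = acc.get((int(a), int(d)), 0.0) + w
    keys = sorted(acc)
    a_old = np.array([k[0] for k in keys])
    gap = np.array([k[1] for k in keys])
    weight = np.array([acc[k] for k in keys])
    return PairAgeDensity(a_old, gap, weight / weight.sum())


# ------------------------------------------------------------ expectations
def expected_ibd_density(model: DemographicModel, bin_edges_morgans,
                         horizon: int | None = None) -> np.ndarray:
    """Expected IBD segment count per haplotype pair per Morgan, per length
    bin (to be scaled by region length L_i and pair count downstream)."""
    edges = np.asarray(bin_edges_morgans, dtype=float)
    if len(edges) < 2:
        raise ValueError("need at least one bin")
    coal = coalescent_pmf(model, horizon)
    g = coal.times.astype(float)
    decay = np.exp(-2.0 * np.outer(g, edges))  # (G, B+1)
    per_edge = (coal.pmf * 2.0 * g) @ decay
    return per_edge[:-1] - per_edge[1:]


def _p_ibd_from_start(model: DemographicModel, u_morgans: np.ndarray,
                      start: int, horizon: int) -> np.ndarray:
    """sum_{t > start} q_start(t) exp(-2 (t - start) u), the probability that
    a pair whose coalescence clock starts at generation ``start`` is unbroken
    across ``u`` (tail beyond the horizon continued at constant size)."""
    hi = start + horizon
    ne = model.ne_trajectory(hi)
    hazard = 1.0 / ne[start:]
    log_surv = np.concatenate([[0.0], np.cumsum(np.log1p(-hazard))])
    q = hazard * np.exp(log_surv[:-1])
    dt = np.arange(1, len(q) + 1, dtype=float)
    out = q @ np.exp(-2.0 * np.outer(dt, u_morgans))
    # analytic geometric tail at constant terminal size
    tail_mass = np.exp(log_surv[-1])
    n_last = ne[-1]
    x = np.exp(-2.0 * u_morgans)
    out += tail_mass * np.exp(-2.0 * len(q) * u_morgans) * (x / n_last) / (
        1.0 - (1.0 - 1.0 / n_last) * x)
    return out


def p_ibd(model: DemographicModel, u_morgans, horizon: int | None = None) -> np.ndarray:
    """Probability a random haplotype pair is unbroken across ``u`` Morgans."""
    if horizon is None:
        horizon = 10 * model.t_max
    u = np.atleast_1d(np.asarray(u_morgans, dtype=float))
    return _p_ibd_from_start(model, u, start=0, horizon=horizon)


def expected_ld(model: DemographicModel, bin_centers_cm, n_haplotypes: float,
                horizon: int | None = None) -> np.ndarray:
    """Expected mean R^2 per distance bin for a panel of ``n_haplotypes``.

    mu_b = p_IBD(u_b) + (1 - p_IBD(u_b)) * beta(n), beta = 4/(n-1)^2.
    """
    if n_haplotypes < 4:
        raise ValueError("need >= 4 effective haplotypes")
    u = np.asarray(bin_centers_cm, dtype=float) / 100.0
    p = p_ibd(model, u, horizon)
    beta = finite_sample_baseline(n_haplotypes, n_haplotypes)
    return p + (1.0 - p) * beta


def expected_ld_time_het(model: DemographicModel, ages: SampleAgeTable,
                         bin_centers_cm, n_haplotypes: float,
                         horizon: int | None = None) -> np.ndarray:
    """Expected mean R^2 with the pair-age density marginalized out.

    p_IBD is replaced by
    ``sum_{(a,gap)} P(a,gap) sum_t q_a(t) exp(-(2t - 2a + gap) u)``:
    the coalescence clock starts at the older sample's age ``a`` and the pair
    is separated by ``2t - 2a + gap`` meioses.  With all ages zero this
    reduces exactly to :func:`expected_ld`.
    """
    if horizon is None:
        horizon = 10 * model.t_max
    u = np.asarray(bin_centers_cm, dtype=float) / 100.0
    dens = pair_age_density(ages)
    p = np.zeros_like(u)
    for a in np.unique(dens.a_old):
        sel = dens.a_old == a
        s_a = _p_ibd_from_start(model, u, start=int(a), horizon=horizon)
        d_a = np.exp(-np.outer(dens.gap[sel].astype(float), u))
        p += s_a * (dens.weight[sel] @ d_a)
    beta = finite_sample_baseline(n_haplotypes, n_haplotypes)
    return p + (1.0 - p) * beta
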