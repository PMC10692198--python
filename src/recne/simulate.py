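"""Scenario library, segment-level coalescent simulation, and fixture generation.

This module is both the package's test oracle and its fixture generator:

* :func:`simulate_pairwise_ibd` draws IBD segments for haplotype pairs from
  the discrete pair coalescent, independently of the analytic expectation
  formulas it is used to validate;
* :func:`simulate_ld_panel` builds genotype panels whose long-range
  correlation is induced by genuinely shared ancestry: msprime ancestry
  simulations are stopped at the coalescent horizon and each local tree root
  ("founder") receives an i.i.d. Bernoulli(p) allele, so sample haplotypes
  are correlated exactly through co-inherited segments;
* :func:`pseudo_haploidize` and :func:`assign_sampling_times` emulate
  low-coverage ancient-DNA data (one sampled allele per site, missingness
  m ~= exp(-coverage), uniform sampling-time offsets).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .demography import DEFAULT_T_MAX, DemographicModel, coalescent_pmf
from .expectations import SampleAgeTable
from .genmap import (BP_PER_CM, GeneticMap, human_arm_table, place_sites,
                     single_arm_table)
from .panel import GenotypePanel

RECOMBINATION_RATE = 1e-8  # per bp per generation; 1 cM/Mb
DEFAULT_HORIZON = 10 * DEFAULT_T_MAX

SCENARIO_NAMES = ("constant", "expansion", "collapse", "bottleneck", "admixture")


@dataclass(frozen=True)
class AdmixtureSpec:
    """Two diverged source populations merging into the sampled one.

    An ancestral population of 10,000 (haploid) splits into two components
    of 5,000 at ``t_split``; they merge with equal contributions at ``t_adm``
    into a population of 10,000 that then follows ``recent_shape``.
    ``t_split`` is parameterized through the fixation index via
    F_st ~= 1 - exp(-t_branch / (2 N_component)).
    """

    fst: float = 0.2
    t_adm: float = 25.0
    recent_shape: str = "constant"
    ne_ancestral: float = 10_000.0
    ne_component: float = 5_000.0

    @property
    def t_split(self) -> float:
        branch = -2.0 * self.ne_component * np.log1p(-self.fst)
        return self.t_adm + branch


@dataclass(frozen=True)
class Scenario:
    name: str
    model: DemographicModel
    admixture: AdmixtureSpec | None = None
    delta_t: float = 0.0


def scenario(name: str, t_max: int = DEFAULT_T_MAX, **kwargs) -> Scenario:
    """Named demographic scenarios (haploid effective sizes).

    constant:   N_e = 20,000 at all times.
    expansion:  200,000 at t=0 shrinking (backward) exponentially to 20,000
                at t=50, constant 20,000 earlier.
    collapse:   2,000 at t=0 growing to 20,000 at t=100.
    bottleneck: 200,000 at t=0, down to 2,000 at t=25, back to 20,000 at
                t=50, constant earlier.
    admixture:  recent single-population shape preceded by a split/merge of
                two diverged components (see :class:`AdmixtureSpec`);
                keyword arguments fst, t_adm, recent_shape.
    """
    if name == "constant":
        return Scenario(name, DemographicModel.constant(20_000.0, t_max))
    if name == "expansion":
        model = DemographicModel.from_knots([0, 50], [200_000.0, 20_000.0], t_max)
        return Scenario(name, model)
    if name == "collapse":
        model = DemographicModel.from_knots([0, 100], [2_000.0, 20_000.0], t_max)
        return Scenario(name, model)
    if name == "bottleneck":
        model = DemographicModel.from_knots([0, 25, 50],
                                            [200_000.0, 2_000.0, 20_000.0], t_max)
        return Scenario(name, model)
    if name == "admixture":
        spec = AdmixtureSpec(**kwargs)
        model = _admixture_recent_model(spec, t_max)
        return Scenario(name, model, admixture=spec)
    raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIO_NAMES}")


def _admixture_recent_model(spec: AdmixtureSpec, t_max: int) -> DemographicModel:
    n0 = spec.ne_ancestral
    if spec.recent_shape == "constant":
        return DemographicModel.from_knots([0, spec.t_adm], [n0, n0], t_max)
    if spec.recent_shape == "expansion":
        return DemographicModel.from_knots([0, spec.t_adm], [100_000.0, n0], t_max)
    if spec.recent_shape == "collapse":
        return DemographicModel.from_knots([0, spec.t_adm], [1_000.0, n0], t_max)
    if spec.recent_shape == "bottleneck":
        return DemographicModel.from_knots([0, spec.t_adm / 2, spec.t_adm],
                                           [n0, 1_000.0, n0], t_max)
    raise ValueError(f"unknown recent shape {spec.recent_shape!r}")


def default_arm_lengths_morgans() -> np.ndarray:
    """Genetic lengths of the default 39-arm genome (36.23 Morgans total)."""
    arms = human_arm_table()
    return ((arms["end_cm"] - arms["start_cm"]) / 100.0).to_numpy()


# ----------------------------------------------------- pairwise IBD oracle
def simulate_pair_coalescence(model: DemographicModel, n_pairs: int, seed: int,
                              horizon: int = DEFAULT_HORIZON) -> np.ndarray:
    """Mechanistic draw of pair coalescence generations (0 = beyond horizon).

    Runs the discrete hazard generation by generation (Bernoulli 1/N_e(g)
    per surviving pair) rather than sampling from the analytic pmf, so it can
    serve as an independent check of :func:`recne.demography.coalescent_pmf`.
    """
    rng = np.random.default_rng(seed)
    ne = model.ne_trajectory(horizon)
    out = np.zeros(n_pairs, dtype=np.int64)
    alive = np.arange(n_pairs)
    for g in range(1, horizon + 1):
        hit = rng.random(alive.size) < 1.0 / ne[g - 1]
        out[alive[hit]] = g
        alive = alive[~hit]
        if alive.size == 0:
            break
    return out


def _length_biased_sampler(model: DemographicModel, horizon: int):
    """Rate of recent-segment starts per Morgan per pair, by generation."""
    coal = coalescent_pmf(model, horizon)
    g = coal.times.astype(float)
    rates = coal.pmf * 2.0 * g
    return g.astype(int), rates


def simulate_pairwise_ibd(scen: Scenario | DemographicModel, n_pairs: int,
                          arm_lengths_morgans=None, seed: int = 0,
                          u_min_morgans: float = 0.02,
                          mode: str = "fast",
                          horizon: int = DEFAULT_HORIZON) -> pd.DataFrame:
    """Draw IBD segments >= ``u_min_morgans`` for haplotype pairs.

    fast mode (default): segments of coalescence generation ``g`` arrive
    along each arm as a marked Poisson process with rate ``2 g q(g)`` per
    Morgan and length Exp(2g) — the stationary form of tiling i.i.d.
    (length-biased) segments, restricted to the recent horizon.  Per-bin
    counts are then exactly Poisson, matching the observation model.

    markov mode: sequential pair path along the arm (coalescence time ``g``
    resampled after each Exp(2g) break), which respects segment-boundary
    geometry at arm ends; much slower, intended for small validation runs.

    Returns a DataFrame (pair, arm, start_m, end_m, length_m, g) where
    coordinates are arm-local Morgans; segments may overhang arm ends in
    fast mode (their full length is retained, as in the stationary process).
    """
    model = scen.model if isinstance(scen, Scenario) else scen
    if arm_lengths_morgans is None:
        arm_lengths_morgans = default_arm_lengths_morgans()
    arm_lengths_morgans = np.asarray(arm_lengths_morgans, dtype=float)
    if np.any(arm_lengths_morgans <= 0):
        raise ValueError("arm lengths must be positive")
    rng = np.random.default_rng(seed)
    if mode == "fast":
        return _simulate_fast(model, n_pairs, arm_lengths_morgans, rng,
                              u_min_morgans, horizon)
    if mode == "markov":
        return _simulate_markov(model, n_pairs, arm_lengths_morgans, rng,
                                u_min_morgans, horizon)
    raise ValueError("mode must be 'fast' or 'markov'")


def _simulate_fast(model, n_pairs, arm_lengths, rng, u_min, horizon):
    gens, rates = _length_biased_sampler(model, horizon)
    total_rate = rates.sum()
    probs = rates / total_rate
    frames = []
    for arm_idx, L in enumerate(arm_lengths):
        n_seg = rng.poisson(total_rate * L * n_pairs)
        if n_seg == 0:
            continue
        g = gens[rng.choice(len(gens), size=n_seg, p=probs)]
        length = rng.exponential(1.0 / (2.0 * g))
        keep = length >= u_min
        g, length = g[keep], length[keep]
        start = rng.uniform(0.0, L, size=g.size)
        frames.append(pd.DataFrame({
            "pair": rng.integers(0, n_pairs, size=g.size),
            "arm": arm_idx + 1,
            "start_m": start,
            "end_m": start + length,
            "length_m": length,
            "g": g,
        }))
    if not frames:
        return pd.DataFrame(columns=["pair", "arm", "start_m", "end_m",
                                     "length_m", "g"])
    return pd.concat(frames, ignore_index=True)


def _draw_stationary_g(coal, rng, size):
    """Locus-marginal coalescence times incl. geometric tail (haploid N)."""
    cdf = np.cumsum(coal.pmf)
    u = rng.random(size)
    g = np.searchsorted(cdf, u) + 1
    in_tail = g > len(coal.pmf)
    if in_tail.any():
        extra = rng.geometric(1.0 / coal.ne_tail, size=int(in_tail.sum()))
        g[in_tail] = len(coal.pmf) + extra
    return g


def _simulate_markov(model, n_pairs, arm_lengths, rng, u_min, horizon):
    """Sequential pair path along each arm.

    Recent segments (g <= horizon) start at rate Lambda = sum_g 2 g q(g) per
    Morgan; the stretches of ancient micro-segments between them are treated
    as a featureless continuum (their individual lengths are far below any
    observable scale), giving exponential inter-start gaps.  Unlike the fast
    mode, segments are laid down sequentially without overlap and are clipped
    at arm boundaries, so arm-end geometry is respected.
    """
    coal = coalescent_pmf(model, horizon)
    g_grid = coal.times
    w = coal.pmf * 2.0 * g_grid.astype(float)
    lam = w.sum()
    cdf = np.cumsum(w) / lam
    rows = []
    for arm_idx, L in enumerate(arm_lengths):
        for pair in range(n_pairs):
            pos = rng.exponential(1.0 / lam)
            while pos < L:
                g = int(np.searchsorted(cdf, rng.random()) + 1)
                end = min(pos + rng.exponential(1.0 / (2.0 * g)), L)
                if end - pos >= u_min:
                    rows.append((pair, arm_idx + 1, pos, end, end - pos, g))
                pos = end + rng.exponential(1.0 / lam)
    return pd.DataFrame(rows, columns=["pair", "arm", "start_m", "end_m",
                                       "length_m", "g"])


def oracle_histogram(segments: pd.DataFrame, arm_lengths_morgans, n_pairs: int,
                     u_min_morgans: float = 0.02):
    """Build an :class:`~recne.ibd.IBDHistogram` directly from simulated
    segments (arm-local coordinates), bypassing file round-trips."""
    from .ibd import IBDHistogram

    arm_lengths_morgans = np.asarray(arm_lengths_morgans, dtype=float)
    lengths_cm = segments["length_m"].to_numpy() * 100.0
    u_min_cm = u_min_morgans * 100.0
    usable = lengths_cm >= u_min_cm - 1e-12
    if not usable.any():
        raise ValueError("no segments above the length threshold")
    max_len = lengths_cm[usable].max()
    n_bins = max(1, int(np.ceil((max_len - u_min_cm) / 0.5 + 1e-9)))
    edges = u_min_cm + 0.5 * np.arange(n_bins + 1)
    regions = np.arange(1, len(arm_lengths_morgans) + 1)
    counts = np.zeros((len(regions), n_bins), dtype=np.int64)
    arm_idx = segments["arm"].to_numpy()[usable] - 1
    b_of = np.minimum(((lengths_cm[usable] - u_min_cm) / 0.5).astype(int), n_bins - 1)
    np.add.at(counts, (arm_idx, b_of), 1)
    return IBDHistogram(regions, edges, counts, arm_lengths_morgans, int(n_pairs))


def segments_to_ibd_file(segments: pd.DataFrame, gmap: GeneticMap, path,
                         n_individuals: int | None = None) -> None:
    """Write oracle segments as a RefinedIBD-style .ibd TSV.

    Pairs are mapped onto (individual, haplotype) labels; arm-local Morgans
    become chromosome-local bp through the map's 1 cM/Mb convention.
    """
    arm_rows = gmap.arms.set_index("arm")
    with open(path, "w") as fh:
        for _, row in segments.iterrows():
            arm = arm_rows.loc[int(row["arm"])]
            arm_len_m = (arm["end_cm"] - arm["start_cm"]) / 100.0
            start_cm = arm["start_cm"] + 100.0 * min(row["start_m"], arm_len_m)
            end_cm = arm["start_cm"] + 100.0 * min(row["end_m"], arm_len_m)
            if end_cm <= start_cm:
                continue  # fully overhanging the arm end
            pair = int(row["pair"])
            i1, i2 = _pair_to_individuals(pair, n_individuals)
            fh.write(f"ind{i1}\t1\tind{i2}\t1\t{int(arm['chrom'])}\t"
                     f"{int(round(start_cm * BP_PER_CM))}\t"
                     f"{int(round(end_cm * BP_PER_CM))}\t"
                     f"{end_cm - start_cm:.6f}\n")


def _pair_to_individuals(pair: int, n_individuals: int | None) -> tuple[int, int]:
    if n_individuals is None:
        return pair, pair + 1_000_000  # synthetic distinct labels
    # enumerate unordered individual pairs
    i = int((1 + np.sqrt(1 + 8 * pair)) // 2)
    j = pair - i * (i - 1) // 2
    return i % n_individuals, j % n_individuals


# ------------------------------------------------------------- LD panels
def _msprime_demography(model: DemographicModel, admixture: AdmixtureSpec | None = None):
    """Translate a haploid piecewise-exponential trajectory into an msprime
    Demography (msprime sizes are diploid: N_e / 2)."""
    import msprime

    demography = msprime.Demography()
    times = model.grid_times
    ne = np.exp(model.log_ne)
    slopes = np.diff(model.log_ne) / np.diff(times)
    demography.add_population(name="pop0", initial_size=ne[0] / 2.0,
                              growth_rate=-slopes[0])
    for k in range(1, len(times) - 1):
        demography.add_population_parameters_change(
            time=times[k], population="pop0", initial_size=ne[k] / 2.0,
            growth_rate=-slopes[k])
    demography.add_population_parameters_change(
        time=times[-1], population="pop0", initial_size=ne[-1] / 2.0,
        growth_rate=0.0)
    if admixture is not None:
        demography.add_population(name="srcA", initial_size=admixture.ne_component / 2.0)
        demography.add_population(name="srcB", initial_size=admixture.ne_component / 2.0)
        demography.add_population(name="anc", initial_size=admixture.ne_ancestral / 2.0)
        demography.add_admixture(time=admixture.t_adm, derived="pop0",
                                 ancestral=["srcA", "srcB"], proportions=[0.5, 0.5])
        demography.add_population_split(time=admixture.t_split,
                                        derived=["srcA", "srcB"], ancestral="anc")
        demography.sort_events()
    return demography


def _founder_classes(ts, positions_bp: np.ndarray) -> np.ndarray:
    """Per (site, sample-node): id of the local-tree root above each sample.

    With the ancestry simulation stopped at the horizon, local roots are the
    'founder' lineages whose alleles samples inherit.
    """
    samples = ts.samples()
    out = np.empty((len(positions_bp), len(samples)), dtype=np.int64)
    tree = ts.first()
    for si, pos in enumerate(positions_bp):
        tree.seek(pos)
        for ni, u in enumerate(samples):
            v = u
            parent = tree.parent(v)
            while parent != -1:
                v = parent
                parent = tree.parent(v)
            out[si, ni] = v
    return out


def _founder_freqs(ts, uniq_roots: np.ndarray, p: float,
                   admixture: AdmixtureSpec | None, rng) -> np.ndarray:
    """Allele frequency each founder lineage draws from.

    Panmictic scenarios use the site frequency ``p`` for every founder.  For
    admixture scenarios, founder lineages sit in one of the two diverged
    source populations at the horizon; each source gets a Balding-Nichols
    frequency Beta(p (1-F)/F, (1-p)(1-F)/F), realizing the scenario's
    fixation index F_st between the sources.
    """
    if admixture is None or admixture.fst <= 0:
        return np.full(len(uniq_roots), p)
    f = admixture.fst
    a, b = p * (1 - f) / f, (1 - p) * (1 - f) / f
    p_src = rng.beta(a, b, size=2)
    pops = ts.nodes_population[uniq_roots]
    src_a = pops == pops.min()
    return np.where(src_a, p_src[0], p_src[1])


def simulate_ld_panel(scen: Scenario | DemographicModel, n_samples: int,
                      sites_per_arm: int = 80,
                      maf_sampler=None, seed: int = 0,
                      arms: pd.DataFrame | None = None,
                      ages: SampleAgeTable | None = None,
                      horizon: int = DEFAULT_HORIZON) -> tuple[GenotypePanel, GeneticMap]:
    """Simulate a diploid genotype panel with ancestry-driven LD.

    Per arm, an msprime ancestry simulation (stopped at the coalescent
    horizon) provides local trees; each site, placed uniformly in cM, gets a
    target minor-allele frequency from ``maf_sampler`` (default
    Uniform(0.25, 0.5)) and its local-tree roots receive i.i.d. Bernoulli(p)
    alleles, which samples inherit.  Sample ages (generations) shift the
    sampling times of the corresponding individuals.
    """
    import msprime

    model = scen.model if isinstance(scen, Scenario) else scen
    admix = scen.admixture if isinstance(scen, Scenario) else None
    if arms is None:
        arms = human_arm_table()
    rng = np.random.default_rng(seed)
    if maf_sampler is None:
        maf_sampler = lambda size: rng.uniform(0.25, 0.5, size=size)
    demography = _msprime_demography(model, admix)
    if ages is not None:
        if ages.n_samples != n_samples:
            raise ValueError("age table size mismatch")
        sample_times = 0.5 * (ages.ages["age_lo"] + ages.ages["age_hi"]).to_numpy()
    else:
        sample_times = np.zeros(n_samples)
    sample_sets = [msprime.SampleSet(1, population="pop0", time=float(t), ploidy=2)
                   for t in sample_times]

    sites_df = place_sites(arms, sites_per_arm, rng)
    geno_cols = []
    order = []
    arm_seeds = rng.integers(1, 2**31 - 1, size=len(arms))
    for (_, arm_row), arm_seed in zip(arms.iterrows(), arm_seeds):
        arm_id = int(arm_row["arm"])
        # arm-local coordinates: bp at 1 cM/Mb
        L_bp = (arm_row["end_cm"] - arm_row["start_cm"]) * BP_PER_CM
        ts = msprime.sim_ancestry(
            samples=sample_sets, demography=demography,
            sequence_length=max(L_bp, 2.0),
            recombination_rate=RECOMBINATION_RATE,
            end_time=horizon, random_seed=int(arm_seed))
        sel = sites_df["arm"] == arm_id
        local_bp = (sites_df.loc[sel, "pos_cm"].to_numpy()
                    - arm_row["start_cm"]) * BP_PER_CM
        local_bp = np.clip(local_bp, 0, L_bp - 1)
        classes = _founder_classes(ts, local_bp)
        p_targets = maf_sampler(int(sel.sum()))
        for row_classes, p in zip(classes, p_targets):
            uniq, inv = np.unique(row_classes, return_inverse=True)
            p_founder = _founder_freqs(ts, uniq, float(p), admix, rng)
            alleles = (rng.random(len(uniq)) < p_founder).astype(float)
            hap = alleles[inv]
            geno_cols.append(hap[0::2] + hap[1::2])
        order.extend(sites_df.index[sel].tolist())
    g = np.column_stack(geno_cols)
    # restore site ordering to match sites_df
    g = g[:, np.argsort(np.asarray(order))]
    panel = GenotypePanel(g, "diploid", [f"ind{i}" for i in range(n_samples)])
    gmap = GeneticMap(sites_df, arms)
    return panel, gmap


def simulate_null_panel(n_samples: int, n_chroms: int = 5,
                        sites_per_chrom: int = 40, maf_sampler=None,
                        seed: int = 0) -> tuple[GenotypePanel, GeneticMap]:
    """Panmictic null panel: independent Binomial(2, p) sites.

    The exact null of the CCLD test (no ancestry-driven correlation at all).
    """
    rng = np.random.default_rng(seed)
    if maf_sampler is None:
        maf_sampler = lambda size: rng.uniform(0.25, 0.5, size=size)
    arms = single_arm_table(n_chroms, 100.0)
    sites = place_sites(arms, sites_per_chrom, rng)
    p = maf_sampler(len(sites))
    g = rng.binomial(2, p[None, :], size=(n_samples, len(sites))).astype(float)
    return GenotypePanel(g, "diploid"), GeneticMap(sites, arms)


def simulate_structured_panel(n_samples: int, fst: float = 0.2,
                              n_chroms: int = 8, sites_per_chrom: int = 50,
                              maf_sampler=None,
                              seed: int = 0) -> tuple[GenotypePanel, GeneticMap]:
    """Panel mixing two diverged subpopulations — current population
    structure, the positive control for the cross-chromosome LD test.

    Half the samples come from each of two groups whose per-site allele
    frequencies are Balding-Nichols draws around a common ancestral
    frequency with fixation index ``fst``; sites are otherwise independent,
    so any cross-chromosome correlation is purely structural.
    """
    rng = np.random.default_rng(seed)
    if maf_sampler is None:
        maf_sampler = lambda size: rng.uniform(0.25, 0.5, size=size)
    arms = single_arm_table(n_chroms, 100.0)
    sites = place_sites(arms, sites_per_chrom, rng)
    m = len(sites)
    p = maf_sampler(m)
    a, b = p * (1 - fst) / fst, (1 - p) * (1 - fst) / fst
    p_sub = rng.beta(a[None, :].repeat(2, 0), b[None, :].repeat(2, 0))
    n_a = n_samples // 2
    g = np.vstack([
        rng.binomial(2, p_sub[0][None, :], size=(n_a, m)),
        rng.binomial(2, p_sub[1][None, :], size=(n_samples - n_a, m)),
    ]).astype(float)
    return GenotypePanel(g, "diploid"), GeneticMap(sites, arms)


# ------------------------------------------------------------- aDNA layers
def coverage_to_missingness(coverage: float) -> float:
    """m ~= exp(-C): chance a site is spanned by no read at coverage C."""
    if coverage < 0:
        raise ValueError("coverage must be >= 0")
    return float(np.exp(-coverage))


def pseudo_haploidize(panel: GenotypePanel, coverage: float | None = None,
                      missingness: float | None = None,
                      seed: int = 0) -> GenotypePanel:
    """Sample one allele per site per individual (doubled), then mask each
    entry as missing with probability ``m`` (``m = exp(-C)`` if coverage is
    given).  Exactly one of ``coverage`` / ``missingness`` must be set
    (``missingness=0`` for pure pseudo-haploidization)."""
    if (coverage is None) == (missingness is None):
        raise ValueError("give exactly one of coverage, missingness")
    m = coverage_to_missingness(coverage) if coverage is not None else float(missingness)
    if not 0.0 <= m < 1.0:
        raise ValueError("missingness must be in [0, 1)")
    rng = np.random.default_rng(seed)
    g = panel.genotypes.copy()
    het = g == 1.0
    g[het] = 2.0 * rng.integers(0, 2, size=int(het.sum()))
    drop = rng.random(g.shape) < m
    g[drop] = np.nan
    return GenotypePanel(g, "pseudo_haploid", list(panel.sample_ids))


def assign_sampling_times(n_samples: int, delta_t: float, seed: int = 0,
                          sample_ids=None) -> SampleAgeTable:
    """Uniform integer sampling-time offsets on [0, delta_t] generations."""
    if delta_t < 0:
        raise ValueError("delta_t must be >= 0")
    rng = np.random.default_rng(seed)
    ages = rng.integers(0, int(round(delta_t)) + 1, size=n_samples)
    ids = sample_ids if sample_ids is not None else [f"ind{i}" for i in range(n_samples)]
    return SampleAgeTable(pd.DataFrame({"sample_id": ids, "age_lo": ages,
                                        "age_hi": ages}))
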