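# Methods

## Problem and model

`recne` infers the recent trajectory of the haploid effective population
size N_e(t) — roughly the last 125 generations — from either of two summary
statistics of a genotype panel:

* **IBD mode**: counts of identity-by-descent segments by length. Two
  haplotypes that coalesce g generations ago are separated by 2g meioses,
  so the segment around any locus they co-inherit has length distributed as
  the minimum-free combination of two Exp(2g) arms; recent ancestors leave
  long segments.
* **LD mode**: mean R² between pairs of sites binned by genetic distance
  within chromosome arms. Long-range LD is driven by the same co-inherited
  segments, so its decay with distance carries the same demographic signal
  without requiring phased or high-quality genotypes.

Time is discrete in generations. A random pair of haploid lineages
coalesces at generation g with probability

    q(g) = (1/N_e(g)) * prod_{u<g} (1 - 1/N_e(u)),

truncated at a horizon G = 10 t_max = 1250 generations with the residual
tail continued analytically at the terminal constant size. From q(g):

* expected IBD segments per haplotype pair per Morgan with length in
  [a, b):  mu_b = sum_g q(g) · 2g · (e^{-2ga} - e^{-2gb});
* probability that a random haplotype pair is unbroken by recombination
  across u Morgans:  p_IBD(u) = sum_g q(g) e^{-2gu}.

The LD observation model is E[R²] = p_IBD(u) + (1 - p_IBD(u)) β, where β is
the finite-sample baseline of the unbiased-style R² estimator

    R² = [ (Σ_i G_ix G_iy)² - Σ_i G²_ix G²_iy ] / (s(s-1)),

computed on genotypes standardized as G = (G̃ - 2p̂)/sqrt(2 p̂ (1-p̂)).
Because the statistic equals the mean of G_ix G_iy G_jx G_jy over distinct
individual pairs, its null expectation is β = 4/((N_x-1)(N_y-1)) with N_x
the observed haplotype count at site x; the same identity underlies the
cross-chromosome structure test. Pseudo-haploid data (one sequencing allele
per site, doubled) keep the Bin(2, p) standardization — the only convention
under which the same β applies with N_x = number of samples. This baseline
algebra is a reconstruction anchored to the estimator's own small-sample
expectation and is validated against Monte-Carlo simulation rather than
against any external implementation.

## Trajectory parameterization and inference

N_e(t) is piecewise exponential: log N_e is linear between the knots of a
time grid on [0, t_max = 125] and constant afterwards. Knots (default 16
intervals) are placed adaptively at equal-mass quantiles of the
observable-ancestor weight w(g) = q(g)·2g·e^{-2g·0.02} (the expected
density of segments above the 2 cM detection floor contributed by ancestors
at generation g); one fit → re-grid → fit round-trip is performed. The
weight's exact form is this package's realization of the equal-expected-
ancestors criterion; the Monte-Carlo oracle, not a reference
implementation, validates it.

The fit maximizes a regularized power likelihood over θ = log N_e at the
knots:

    objective(θ) = c · Σ_{i,b} nll(Y_ib | μ_b(θ)) + λ · Σ_k (Δslope_k · w̄)²

* IBD: Y_ib ~ quasi-Poisson with mean μ_b(θ) L_i n_pairs and per-bin
  dispersion φ²_b = max(1, Pearson X²/(R-1)) estimated from a pilot fit
  (negative log-likelihood = half-deviance / φ²_b).
* LD: Y_ib ~ Normal with mean p_b + (1-p_b)·baseline_ib. The observation
  variance is estimated per bin from the cross-region spread of Y (regions
  rescaled by their relative pair counts) and frozen for all resampled
  refits. Pair-level within-bin variances are reported in the summary
  tables but are deliberately not used as likelihood weights: with few,
  mutually correlated pairs per bin they are unstable enough to dominate
  the fit.
* The prior penalizes fluctuations of log N_e: squared changes of its
  growth rate between adjacent grid intervals (slopes differenced, scaled
  by the mean interval width), plus the squared growth rate itself at a
  fixed mild weight (0.1) inside the same λ. A constant history costs
  nothing and a single exponential costs only the small slope term, so
  regularization favors constant and exponential shapes; the slope term
  exists because curvature alone leaves a global exponential tilt free,
  which weakly informative panels otherwise fill with noise. As λ → ∞ the
  fit loses all curvature and shrinks to the best constant. A smooth
  trajectory on weak data therefore reflects absent evidence, not evidence
  of constancy.

Hyperparameters are self-tuned. The exponent c discounts correlation
between the bins of a region: residuals of a pilot fit give a mean absolute
lag-1 autocorrelation r per region, the effective number of independent
bins is n_bins(1-r), and c = 1-r snapped to the grid {1, 1/2, 1/4, …,
1/n_bins} (independent bins → 1, duplicated bins → 1/2, a fully correlated
region → 1/n_bins). λ is chosen by leave-regions-out cross-validation over
{0.1, 1, 10, 100, 1000} with the one-standard-error rule — the strongest λ
statistically indistinguishable from the CV optimum — so weak data get
strong smoothing.

Optimization is bounded L-BFGS-B over log N_e ∈ [log 10, log 10⁸] with
multi-start (constant at a moment-based guess; best two-parameter
exponential; pilot solution). The genetic-distance decay matrices depend
only on the bin layout, so they are precomputed once and each objective
evaluation is a hazard cumulative sum plus one matrix-vector product.

Uncertainty: chromosome arms are the unit of independence. 100 bootstrap
replicates resample kept arms with replacement and refit with the grid, c
and λ frozen; per-generation 2.5/25/75/97.5 percentiles give 95% and 50%
bands. Up to 10% failed replicates are tolerated and recorded.

## Quality control

* **Region filters.** LD: per-bin center and scale from the cross-region
  median and IQR/1.349 (robust to the outliers being hunted); an arm is
  dropped if any bin deviates by more than 6 scale units or if its values
  never cross the median (ties count as crossing — the rule targets
  systematic one-sided shifts). IBD: leave-one-out Poisson means and
  dispersions per bin; an arm is dropped when its dispersion-scaled squared
  deviance-residual sum leaves the central 1-2α mass of χ² (α = 1e-12,
  df = number of contributing bins; all-empty bins contribute nothing);
  the procedure runs exactly twice. When a leave-one-out mean is zero but
  the count is positive, the mean is floored at half a count.
* **Structure test.** For sampled cross-chromosome site pairs the mean over
  distinct individual pairs of G_ix G_iy G_jx G_jy − 4/((N_x−1)(N_y−1)) is
  averaged per chromosome pair; a one-sample two-sided t-test across
  chromosome pairs flags significant cross-chromosome LD (α = 0.05). The
  test warns — admixture LD decays with distance and can mimic a recent
  contraction — but never aborts a run. Chromosome-pair means sharing a
  chromosome are mildly dependent, so the test runs a little above its
  nominal level (~8% at 5 chromosomes in our null calibration); it is a
  flag, not a calibrated p-value.

## Ancient DNA

* Pseudo-haploid panels store the sampled allele doubled ({0, 2}); the
  effective haplotype count per site is the number of samples. Missingness
  relates to sequencing coverage as m ≈ e^{-C}; it affects expectations
  only through the per-site observation counts entering β.
* Heterogeneous sampling times: each sample carries an age interval in
  generations (helper for years with a 29 years/generation default). The
  density of (age of the older sample a, age gap) over random pairs is
  enumerated exactly from the per-sample uniform intervals; the coalescence
  clock starts at a and the pair is separated by 2t − 2a + gap meioses, so

      p_IBD(u) = Σ_{(a,gap)} P(a,gap) Σ_t q_a(t) e^{-(2t-2a+gap)u}.

  With all ages zero this reduces exactly to the contemporaneous formula.
  Ignoring true age spread inflates recent N_e (the extra meioses decay LD,
  which a contemporaneous model attributes to a larger population).

## Synthetic data: what it emulates and what it does not

The simulator is both fixture generator and test oracle, deliberately
independent of the expectation formulas where that matters.

* **Pairwise IBD ("fast" mode).** Segments with coalescence generation g
  arrive along an arm as a marked Poisson process at rate 2g·q(g) per
  Morgan with length Exp(2g) — the stationary form of tiling i.i.d.
  length-biased segments. Per-bin counts are then exactly Poisson with mean
  μ_b·L, i.e. the observation model itself; segments may overhang arm ends.
  A sequential "markov" mode lays recent segments down without overlap and
  clips at arm boundaries (ancient micro-segments are treated as a
  featureless continuum between them); it is slower and used for
  boundary-geometry checks.
* **Genotype panels.** Per arm, an msprime ancestry simulation (haploid
  sizes divided by two for msprime's diploid convention; continuous-time
  Hudson model) is stopped at the coalescent horizon; each local tree root
  is a "founder" that receives an i.i.d. Bernoulli(p) allele with p from
  the MAF sampler (default Uniform(0.25, 0.5), matching the pipeline's
  MAF > 0.25 filter), and samples inherit alleles through the trees. LD
  thus arises from genuinely shared ancestry with tree-consistent sharing
  patterns — an independent check of the Sved-style pairwise expectation,
  not a re-implementation of it. Admixture scenarios additionally draw
  per-source founder frequencies from a Balding–Nichols Beta with the
  scenario's F_st (the split predates the horizon). Sampling-time offsets
  become msprime sample times.
* **Null panels** for the structure test are independent Binomial(2, p)
  sites — the exact null.
* **Scenario library** (haploid sizes): constant 20,000; expansion 200,000
  → 20,000 at t=50; collapse 2,000 → 20,000 at t=100; bottleneck 200,000 →
  2,000 at t=25 → 20,000 at t=50; admixture variants (ancestral 10,000
  splitting into two of 5,000, merging with equal proportions at t_adm,
  F_st ≈ 1 − e^{−t_branch/(2N)} labeling the divergence). The default
  genome has 39 chromosome arms totaling 36.23 Morgans with approximate
  human arm proportions; synthetic physical coordinates use 1 cM/Mb.

What the generator does **not** emulate: mutation and allele-frequency
drift over time (site frequencies are constant, as in the inference model);
IBD detection error (oracle segments are exact, so IBD-mode results bound
what detected segments can give); genotyping or phasing error; linked
selection or structural variation (the region filters are exercised with
synthetic outliers instead). Passing tests therefore demonstrate
correctness of the estimator given its model class, not robustness to
call-level artifacts in real data.

## Numerical choices and conventions

* Haploid N_e throughout; diploid census ≈ N_e/2.
* Horizon G = 1250 everywhere (model, simulator founder threshold);
  truncation error at the shortest modeled distance is O(e^{-12.5}).
* Half-open bins: distances and lengths fall in [lo, hi); 0.5 cM width; LD
  window default [0.5, 30) cM (1/(2·0.005) = 100 and 1/(2·0.30) ≈ 1.7
  generations bracket the target epoch); IBD lengths from 2 cM to the
  longest observed segment.
* Pairwise-complete missing-data handling: R² sums run over jointly
  observed individuals with s the overlap; bins with no pairs are masked,
  never imputed; pair counts per bin capped at 10⁶ (seeded subsample).
* IBD segments are assigned to the arm containing their midpoint;
  centromere-spanning segments are split at the boundary so arms stay
  disjoint resampling units. Self-pairs are excluded; a diploid pair
  contributes 4 haplotype pairs.
* Fits are deterministic given the configuration seed; one master seed fans
  out to per-replicate seeds.
* Degenerate inputs: monomorphic sites must be filtered before
  standardization (internal error otherwise); a single region disables
  dispersion estimation (φ² = 1) and cross-region variance pooling; empty
  IBD inputs fail naming the 2 cM threshold.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run the scenario recoveries at
desk scale: LD panels of 100 diploids on 20 arms of 40 cM with 150 sites
per arm (roughly the density of a MAF-filtered SNP array), IBD oracles of
10⁵ haplotype pairs on the 39-arm genome, 200 replicate panels for the
structure-test calibration, and bootstrap counts reduced where only the
point estimate is asserted. Tolerances are the ones
stated with each check (±30% for constant-size recovery, factor 2 for
collapse/bottleneck sizes, 3 SE for oracle agreement); only replicate
counts and panel sizes are scaled, never the tolerances.

## Known limitations

* Single panmictic population; admixture and structure are detected and
  flagged, not modeled. Residual admixture LD can still bias LD-mode fits
  toward a spurious recent contraction.
* IBD mode trusts its input segments; type-1/type-2 detection errors are
  not modeled.
* The LD likelihood treats bins as Normal with a shared per-bin variance;
  very sparse panels (few usable pairs per bin) push that approximation.
* The structure test's t-statistic ignores the overlap between chromosome
  pairs (see above).
* Time heterogeneity is corrected marginally over the pair-age density, not
  per pair.
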