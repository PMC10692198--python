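# recne

**Recent effective population size inference from IBD segments or linkage
disequilibrium.**

`recne` reconstructs the haploid effective population size N_e(t) of a
population over roughly the last 125 generations (~2000 years for humans)
from either of two signals left by recent shared ancestry:

* **IBD mode** — the length spectrum of identity-by-descent segments
  (detected externally by tools such as HapIBD or RefinedIBD; `recne` reads
  their output). Recent common ancestors transmit long segments, so the
  counts of segments per length bin encode the density of ancestors per
  generation.
* **LD mode** — the decay of long-range linkage disequilibrium with genetic
  distance. Long-range LD is driven by the same co-inherited segments, but
  R² statistics need neither phasing nor high-quality calls, which makes
  this mode usable on SNP-array panels and on low-coverage, pseudo-haploid
  ancient-DNA data with heterogeneous sampling dates.

It is intended for population geneticists analyzing modern cohorts,
underrepresented populations without good reference panels, and
ancient-DNA sample sets.

## Model

A random pair of haploid lineages coalesces at generation g with
probability q(g) = N_e(g)⁻¹ ∏_{u<g} (1 − N_e(u)⁻¹). Conditional on
coalescence at g, segment boundaries occur at rate 2g per Morgan, giving

* expected IBD segment counts per pair per Morgan in a length bin [a, b):
  μ_b = Σ_g q(g) · 2g · (e^(−2ga) − e^(−2gb)), modeled as (quasi-)Poisson
  per chromosome arm;
* expected mean R² at genetic distance u:
  p_IBD(u) + (1 − p_IBD(u)) β, with p_IBD(u) = Σ_g q(g) e^(−2gu) and β the
  finite-sample baseline of the unbiased-style R² estimator
  R² = [(Σ_i G_ix G_iy)² − Σ_i G²_ix G²_iy]/(s(s−1)) on standardized
  genotypes, modeled as Normal per arm and distance bin.

N_e(t) is piecewise exponential on an adaptive time grid and constant
beyond t_max = 125. The fit maximizes a power likelihood (exponent c
discounts between-bin correlation) plus a smoothness prior on log N_e; c
and the prior strength are tuned automatically. Chromosome arms are
resampled with replacement (100 replicates) for 50%/95% confidence bands.
Quality control includes robust per-arm outlier filters for both statistics
and a cross-chromosome-LD test that flags population structure/admixture,
whose LD can masquerade as a recent contraction. For non-contemporaneous
samples, per-sample age ranges are marginalized out through the density of
pair ages, removing the spurious recent expansion that unmodeled sampling
times produce. `docs/methods.md` has the full account.

## Worked example

`examples/infer_from_ld.py` simulates a 100-diploid panel (12 chromosome
arms of 40 cM) under a constant haploid N_e = 20,000 and runs the full LD
pipeline:

```
$ python examples/infer_from_ld.py
kept 12/12 arms; CCLD p = 0.698
geometric mean N_e over t=1..50: 20,404 (simulated: 20,000)

  t    N_e_map      95% band
   1     20,776   [15,958, 36,123]
  10     20,648   [15,872, 36,013]
  25     20,423   [15,635, 35,802]
  50     19,996   [15,110, 35,365]
 100     18,934   [13,994, 34,186]
```

The trajectory recovers the simulated size within a few percent; the
non-significant CCLD p-value says no structure-driven LD was detected. The other scripts
in `examples/` demonstrate IBD-based inference of a bottleneck, ancient
pseudo-haploid panels with heterogeneous sampling times, the structure
test, and the analytic expectation curves.

A thin CLI wraps the same pipelines:

```
recne simulate bottleneck --out fix --n 100 --n-ibd-pairs 100000
recne ld  --genotypes fix --map fix.map.tsv --out run_ld
recne ibd --ibd fix.ibd   --map fix.map.tsv --out run_ibd
```

Outputs are TSV trajectories (`.ne.tsv`: generation, MAP N_e, 2.5/25/75/
97.5% bands), filter and CCLD reports, and a JSON diagnostics file
recording every tuned hyperparameter.

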