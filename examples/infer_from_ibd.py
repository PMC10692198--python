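"""Infer a bottleneck from IBD segment length counts.

Simulates pairwise IBD segments (>= 2 cM) under a bottleneck demography
(200,000 -> 2,000 at t = 25 -> 20,000 at t = 50, haploid sizes) with the
segment-level coalescent simulator, builds the per-arm length histogram, and
fits the quasi-Poisson trajectory model.  The printed minimum of the
trajectory should land within a factor ~2 of the simulated minimum, 2,000.
"""

import numpy as np

from recne import FitConfig, run_ibd_pipeline, scenario, simulate_pairwise_ibd
from recne.simulate import default_arm_lengths_morgans, oracle_histogram

lengths = default_arm_lengths_morgans()  # 39 human-like arms, 36.23 Morgans
n_pairs = 100_000
segments = simulate_pairwise_ibd(scenario("bottleneck"), n_pairs, lengths, seed=7)
print(f"simulated {len(segments):,} segments >= 2 cM across {len(lengths)} arms")

hist = oracle_histogram(segments, lengths, n_pairs)
result = run_ibd_pipeline(hist, None, FitConfig(seed=7, n_bootstrap=0))

model = result.posterior.map_model
gens = np.arange(15, 41)
t_min = gens[np.argmin(model.ne_at(gens))]
print(f"inferred minimum N_e = {model.ne_at(float(t_min)):,.0f} at t = {t_min} "
      "(simulated: 2,000 at t = 25)")
for t in (1, 15, 25, 40, 75, 125):
    print(f"  t={t:3d}  N_e = {model.ne_at(float(t)):10,.0f}")
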