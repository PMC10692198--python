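"""Trajectory plotting helper."""

from __future__ import annotations

import numpy as np

from .demography import DemographicModel
from .inference import NePosterior


def plot_posterior(posterior: NePosterior, ax=None,
                   truth: DemographicModel | None = None,
                   generation_years: float | None = None):
    """Plot the MAP N_e trajectory with its 50%/95% bootstrap bands.

    The x axis is generations before present (or years, when
    ``generation_years`` is given); the y axis is haploid N_e on a log
    scale.  Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    gens = np.arange(1, posterior.map_model.t_max + 1)
    x = gens * generation_years if generation_years else gens
    q = posterior.quantiles
    if {"q2.5", "q97.5"} <= q.keys():
        ax.fill_between(x, q["q2.5"], q["q97.5"], alpha=0.2, lw=0, label="95%")
    if {"q25", "q75"} <= q.keys():
        ax.fill_between(x, q["q25"], q["q75"], alpha=0.35, lw=0, label="50%")
    ax.plot(x, posterior.map_model.ne_at(gens), lw=2, label="MAP")
    if truth is not None:
        ax.plot(x, truth.ne_at(gens), "k--", lw=1, label="truth")
    ax.set_yscale("log")
    ax.set_xlabel("years before present" if generation_years
                  else "generations before present")
    ax.set_ylabel("haploid $N_e$")
    ax.legend(frameon=False)
    return ax
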