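"""End-to-end LD and IBD inference pipelines.

These are the library-level entry points the CLI wraps: they chain summary
computation, quality-control filtering, the structure test, MAP fitting and
the chromosome-arm bootstrap, and collect every decision in a result object.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expectations import SampleAgeTable
from .filters import filter_ibd_regions, filter_ld_regions
from .genmap import GeneticMap
from .ibd import IBDHistogram, build_ibd_histogram, read_ibd
from .inference import FitConfig, NePosterior, bootstrap_ci, fit_map
from .ld import (DEFAULT_MAF_MIN, DEFAULT_WINDOW_CM, BinnedLD, CCLDReport,
                 bin_ld_curve, ccld_test)
from .panel import GenotypePanel

logger = logging.getLogger("recne")


@dataclass
class PipelineResult:
    posterior: NePosterior
    summary: BinnedLD | IBDHistogram
    kept_regions: np.ndarray
    filter_report: pd.DataFrame
    ccld: CCLDReport | None = None
    warnings: list = field(default_factory=list)

    def write(self, prefix: str) -> None:
        self.posterior.to_tsv(prefix + ".ne.tsv")
        self.posterior.diagnostics_json(prefix + ".diagnostics.json")
        self.filter_report.to_csv(prefix + ".filter.tsv", sep="\t", index=False)
        if isinstance(self.summary, BinnedLD):
            self.summary.to_tsv(prefix + ".binned_ld.tsv")
        else:
            self.summary.to_tsv(prefix + ".ibd_hist.tsv")
        if self.ccld is not None and self.ccld.applicable:
            self.ccld.to_tsv(prefix + ".ccld.tsv")


def run_ld_pipeline(panel: GenotypePanel, gmap: GeneticMap,
                    ages: SampleAgeTable | None = None,
                    config: FitConfig | None = None,
                    window_cm=DEFAULT_WINDOW_CM,
                    maf_min: float = DEFAULT_MAF_MIN) -> PipelineResult:
    """LD branch: MAF filter -> binned R^2 -> CCLD test -> region filter ->
    MAP fit (+ age marginalization) -> bootstrap bands.

    A significant CCLD test flags possible admixture LD and is logged as a
    warning (results may be biased toward a spurious recent contraction) but
    never aborts the run.
    """
    config = config or FitConfig()
    warns = []
    logger.info("LD pipeline: %d samples (%s), %d sites, MAF > %.2f, "
                "window [%.1f, %.1f) cM", panel.n_samples, panel.ploidy_mode,
                panel.n_sites, maf_min, *window_cm)
    ld = bin_ld_curve(panel, gmap, window_cm=window_cm, maf_min=maf_min,
                      seed=config.seed)
    ccld = ccld_test(panel, gmap, maf_min=maf_min, seed=config.seed)
    if ccld.applicable:
        logger.info(ccld.summary())
        if ccld.significant:
            msg = ("admixture LD detected: cross-chromosome LD is significant; "
                   "inferred trajectories may be biased")
            warns.append(msg)
            logger.warning(msg)
    kept, report = filter_ld_regions(ld)
    logger.info("LD region filter kept %d/%d regions", len(kept), len(ld.regions))
    data = ld.subset(kept)
    post = fit_map(data, config, ages)
    if config.n_bootstrap > 0:
        post = bootstrap_ci(data, config, ages, post)
    post.diagnostics["ccld_p_value"] = None if not ccld.applicable else ccld.p_value
    post.diagnostics["ccld_significant"] = bool(ccld.significant) if ccld.applicable else None
    post.diagnostics["kept_regions"] = list(map(int, kept))
    return PipelineResult(post, ld, kept, report, ccld, warns)


def run_ibd_pipeline(ibd_source, gmap: GeneticMap,
                     config: FitConfig | None = None,
                     u_min_cm: float = 2.0,
                     n_pairs: int | None = None) -> PipelineResult:
    """IBD branch: read segments -> length histogram (>= u_min) -> region
    filter -> dispersion -> MAP fit -> bootstrap bands.

    ``ibd_source`` is a path to a RefinedIBD/HapIBD-style TSV, a segment
    list, or a prebuilt :class:`IBDHistogram`.
    """
    config = config or FitConfig()
    if isinstance(ibd_source, IBDHistogram):
        hist = ibd_source
    else:
        segments = (read_ibd(ibd_source, gmap)
                    if isinstance(ibd_source, (str, bytes)) or hasattr(ibd_source, "__fspath__")
                    else ibd_source)
        hist = build_ibd_histogram(segments, gmap, u_min_cm=u_min_cm,
                                   n_pairs=n_pairs)
    logger.info("IBD pipeline: %d regions, %d bins, %d segments >= %.1f cM",
                len(hist.regions), hist.n_bins, int(hist.counts.sum()), u_min_cm)
    kept, report = filter_ibd_regions(hist)
    logger.info("IBD region filter kept %d/%d regions", len(kept), len(hist.regions))
    data = hist.subset(kept)
    post = fit_map(data, config)
    if config.n_bootstrap > 0:
        post = bootstrap_ci(data, config, None, post)
    post.diagnostics["kept_regions"] = list(map(int, kept))
    return PipelineResult(post, hist, kept, report)
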