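"""Outlier chromosome-arm filtering for LD and IBD summaries.

Regions carrying unusually high (or low) LD or IBD sharing — natural
selection, structural variation, assembly artifacts — would bias demographic
inference and are dropped before fitting.  Both filters use robust
cross-region statistics so the outliers being hunted cannot poison the
reference distribution.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .ibd import IBDHistogram
from .ld import BinnedLD

#: IQR of a standard normal; IQR / 1.349 is a normal-consistent robust scale.
_NORMAL_IQR = 1.349
DEFAULT_LD_SD_LIMIT = 6.0
DEFAULT_IBD_ALPHA = 1e-12


def filter_ld_regions(ld: BinnedLD, sd_limit: float = DEFAULT_LD_SD_LIMIT
                      ) -> tuple[np.ndarray, pd.DataFrame]:
    """Drop arms with outlying LD.

    Per bin, center/scale are the cross-region median and IQR/1.349.  An arm
    is dropped if any bin deviates from the median by more than ``sd_limit``
    scale units, or if its values never cross the median (all strictly above
    or all strictly below — a systematic one-sided shift; bins tied with the
    median count as crossing).
    """
    usable_idx = np.where(ld.usable)[0]
    if len(usable_idx) < 3:
        raise ValueError("LD region filter needs >= 3 usable regions")
    y = ld.y[usable_idx]
    med = np.nanmedian(y, axis=0)
    q75, q25 = np.nanpercentile(y, [75, 25], axis=0)
    scale = (q75 - q25) / _NORMAL_IQR
    # with few regions the IQR occasionally collapses by chance; floor each
    # bin's scale against the typical scale across bins so chance-tight
    # quantiles do not manufacture extreme z-scores
    typical = np.nanmedian(scale[scale > 0]) if np.any(scale > 0) else 0.0
    scale = np.maximum(scale, 0.3 * typical)
    dev = y - med[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(dev == 0, 0.0, dev / np.where(scale > 0, scale, np.nan))
    rows, kept = [], []
    for k, ri in enumerate(usable_idx):
        finite = ~np.isnan(y[k])
        worst = np.nanmax(np.abs(z[k])) if np.any(~np.isnan(z[k])) else 0.0
        crosses = bool(np.any(dev[k][finite] <= 0) and np.any(dev[k][finite] >= 0))
        keep = (worst <= sd_limit) and crosses
        reason = "" if keep else ("deviation" if worst > sd_limit else "one-sided")
        rows.append((ld.regions[ri], worst, crosses, keep, reason))
        if keep:
            kept.append(ld.regions[ri])
    for ri in np.where(~ld.usable)[0]:
        rows.append((ld.regions[ri], np.nan, False, False, "unusable"))
    report = pd.DataFrame(rows, columns=["region", "worst_z", "crosses_median",
                                         "kept", "reason"])
    if not kept:
        raise ValueError("all regions dropped by the LD filter; inspect the "
                         "binned LD table before proceeding")
    return np.array(kept), report


def _ibd_pass(counts: np.ndarray, lengths: np.ndarray, alpha: float):
    """One leave-one-out deviance pass; returns (keep mask, per-region stats)."""
    n_regions, n_bins = counts.shape
    keep = np.ones(n_regions, dtype=bool)
    stats_rows = []
    lo_q = None
    for i in range(n_regions):
        others = np.arange(n_regions) != i
        pooled_rate = counts[others].sum(axis=0) / lengths[others].sum()
        mu_other = np.outer(lengths[others], pooled_rate)
        with np.errstate(invalid="ignore", divide="ignore"):
            pearson = (counts[others] - mu_other) ** 2 / mu_other
        n_other = others.sum()
        phi = np.ones(n_bins)
        if n_other > 1:
            x2 = np.nansum(np.where(mu_other > 0, pearson, 0.0), axis=0)
            phi = np.maximum(1.0, x2 / (n_other - 1))
        mu_i = lengths[i] * pooled_rate
        y = counts[i].astype(float)
        used = (mu_i > 0) | (y > 0)
        # floor mu at half a count where the loo-mean is zero but y > 0
        mu_safe = np.where(mu_i > 0, mu_i, 0.5)
        with np.errstate(invalid="ignore", divide="ignore"):
            logterm = np.where(y > 0, y * np.log(y / mu_safe), 0.0)
        dev2 = 2.0 * (logterm - (y - mu_safe)) / phi
        dev2 = np.where(used, dev2, 0.0)
        d_total = float(np.sum(dev2))
        df = int(used.sum())
        lo_q = stats.chi2.ppf(alpha, df)
        hi_q = stats.chi2.ppf(1.0 - alpha, df)
        inside = lo_q <= d_total <= hi_q
        keep[i] = inside
        stats_rows.append((d_total, df, lo_q, hi_q, inside))
    return keep, stats_rows


def filter_ibd_regions(hist: IBDHistogram, alpha: float = DEFAULT_IBD_ALPHA
                       ) -> tuple[np.ndarray, pd.DataFrame]:
    """Drop arms whose IBD counts misfit the cross-region Poisson model.

    For each arm, per-bin Poisson means and dispersion factors come from all
    other (still active) arms; the arm is dropped when its dispersion-scaled
    squared deviance residual sum leaves the central ``1 - 2 alpha`` mass of
    the chi-square with df = number of contributing bins.  The procedure runs
    exactly twice, the second pass without the arms dropped in the first.
    """
    if len(hist.regions) < 3:
        raise ValueError("IBD region filter needs >= 3 regions")
    active = np.ones(len(hist.regions), dtype=bool)
    rows = []
    for pass_no in (1, 2):
        idx = np.where(active)[0]
        keep, st = _ibd_pass(hist.counts[idx], hist.lengths_morgans[idx], alpha)
        for k, ri in enumerate(idx):
            d_total, df, lo_q, hi_q, inside = st[k]
            rows.append((hist.regions[ri], pass_no, d_total, df, lo_q, hi_q, inside))
        active[idx[~keep]] = False
    report = pd.DataFrame(rows, columns=["region", "pass", "deviance_sum", "df",
                                         "chi2_lo", "chi2_hi", "kept"])
    kept = hist.regions[active]
    if len(kept) == 0:
        raise ValueError("all regions dropped by the IBD filter; inspect the "
                         "histogram before proceeding")
    return kept, report
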