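"""Unbiased-style R^2 statistics, distance-binned LD curves, and the
cross-chromosome LD (CCLD) test for population structure.

The LD between two sites is measured on standardized genotypes
``G = (G_tilde - 2 p_hat) / sqrt(2 p_hat (1 - p_hat))`` as

    R^2 = [ (sum_i G_ix G_iy)^2 - sum_i G_ix^2 G_iy^2 ] / (s (s - 1)),

with sums over jointly observed individuals and ``s`` the overlap count.
Subtracting the squared terms removes the diagonal of the double sum, so the
statistic is the mean of ``G_ix G_iy G_jx G_jy`` over distinct individual
pairs: it is unbiased-style (possibly negative) and its expectation under
independent sites is the finite-sample baseline ``4/((N_x-1)(N_y-1))``
(``N_x`` = observed haplotypes at site x).  Correlation between unlinked
sites in excess of that baseline is the signature of population structure
exploited by the CCLD test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genmap import GeneticMap
from .panel import GenotypePanel

DEFAULT_BIN_WIDTH_CM = 0.5
DEFAULT_WINDOW_CM = (0.5, 30.0)
DEFAULT_MAF_MIN = 0.25
DEFAULT_PAIR_CAP = 1_000_000


def standardize(panel: GenotypePanel) -> np.ndarray:
    """Standardized genotype matrix; missing entries stay NaN.

    Allele frequencies are estimated from non-missing entries.  Both diploid
    and pseudo-haploid panels use the Bin(2, p) denominator
    ``sqrt(2 p_hat (1-p_hat))`` (pseudo-haploid calls are the sampled allele
    doubled); this is the convention under which the cross-individual product
    has null expectation ``4/((N_x-1)(N_y-1))`` in haplotype counts.
    """
    g = panel.genotypes
    p = panel.allele_freq()
    if np.any((p <= 0) | (p >= 1)):
        raise RuntimeError("monomorphic site reached standardization; filter first")
    return (g - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))


def pairwise_r2(gx: np.ndarray, gy: np.ndarray) -> float:
    """R^2 of two standardized columns over jointly observed individuals."""
    mask = ~np.isnan(gx) & ~np.isnan(gy)
    s = int(mask.sum())
    if s < 2:
        return np.nan
    x, y = gx[mask], gy[mask]
    t = np.sum(x * y)
    q = np.sum(x * x * y * y)
    return float((t * t - q) / (s * (s - 1)))


def _r2_matrices(G: np.ndarray):
    """All-pairs R^2 (and overlap counts) for a standardized block.

    Returns (r2, overlap) as k x k matrices; entries with overlap < 2 are NaN.
    """
    obs = ~np.isnan(G)
    Z = np.where(obs, G, 0.0)
    S = Z.T @ Z
    Q = (Z * Z).T @ (Z * Z)
    O = obs.astype(float).T @ obs.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = (S * S - Q) / (O * (O - 1.0))
    r2[O < 2] = np.nan
    return r2, O


def _site_baseline(panel: GenotypePanel) -> np.ndarray:
    """Per-site observed-haplotype counts N_x."""
    ploidy = 1 if panel.ploidy_mode == "pseudo_haploid" else 2
    return ploidy * panel.site_call_counts().astype(float)


def finite_sample_baseline(n_x, n_y) -> np.ndarray:
    """Null expectation of the R^2 statistic: 4 / ((N_x - 1)(N_y - 1))."""
    return 4.0 / ((np.asarray(n_x, float) - 1.0) * (np.asarray(n_y, float) - 1.0))


@dataclass
class BinnedLD:
    """Mean R^2 per (chromosome arm, genetic-distance bin).

    ``y``, ``var``, ``n_pairs`` and ``baseline`` are (region x bin) arrays;
    bins with no pairs are NaN-masked (never imputed).  ``baseline`` holds the
    mean finite-sample null expectation of the pairs in the bin, and
    ``n_haplotypes`` the panel-wide mean observed-haplotype count, used by the
    expectations module.
    """

    regions: np.ndarray
    bin_edges: np.ndarray
    y: np.ndarray
    n_pairs: np.ndarray
    var: np.ndarray
    baseline: np.ndarray
    n_haplotypes: float
    ploidy_mode: str = "diploid"
    usable: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.usable is None:
            self.usable = np.sum(~np.isnan(self.y), axis=1) >= 2

    @property
    def bin_centers_cm(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges) - 1

    def subset(self, region_ids) -> "BinnedLD":
        """Restrict (or resample, ids may repeat) to the given region ids."""
        pos = {r: i for i, r in enumerate(self.regions)}
        idx = np.array([pos[r] for r in region_ids], dtype=int)
        return BinnedLD(np.asarray(region_ids), self.bin_edges, self.y[idx],
                        self.n_pairs[idx], self.var[idx], self.baseline[idx],
                        self.n_haplotypes, self.ploidy_mode)

    def to_tsv(self, path) -> None:
        rows = []
        for i, reg in enumerate(self.regions):
            for b in range(self.n_bins):
                rows.append((reg, self.bin_edges[b], self.bin_edges[b + 1],
                             self.y[i, b], int(self.n_pairs[i, b]), self.var[i, b],
                             self.baseline[i, b]))
        pd.DataFrame(rows, columns=["region", "bin_lo_cm", "bin_hi_cm", "mean_r2",
                                    "n_pairs", "var", "baseline"]).to_csv(
            path, sep="\t", index=False)


def bin_ld_curve(panel: GenotypePanel, gmap: GeneticMap,
                 window_cm: tuple[float, float] = DEFAULT_WINDOW_CM,
                 maf_min: float = DEFAULT_MAF_MIN,
                 bin_width_cm: float = DEFAULT_BIN_WIDTH_CM,
                 pair_cap: int = DEFAULT_PAIR_CAP,
                 seed: int = 0) -> BinnedLD:
    """Bin pairwise R^2 by genetic distance within chromosome arms.

    Sites are filtered to MAF > ``maf_min`` and >= 2 calls; pairs are
    restricted to the same arm with distance in ``[window_cm[0],
    window_cm[1])`` and assigned to half-open 0.5 cM bins.  Per bin, the
    within-bin variance of pair values is divided by an effective count
    (pairs divided by the mean number of pairs each site participates in) to
    acknowledge that pairs sharing a site are correlated.
    """
    if gmap.n_sites != panel.n_sites:
        raise ValueError("map/site mismatch")
    lo, hi = window_cm
    edges = np.arange(lo, hi + 0.5 * bin_width_cm, bin_width_cm)
    n_bins = len(edges) - 1
    p = panel.allele_freq()
    calls = panel.site_call_counts()
    maf = np.minimum(p, 1 - p)
    keep = (maf > maf_min) & (calls >= 2)
    G = np.full(panel.genotypes.shape, np.nan)
    sub = panel.drop_sites(keep)
    G[:, keep] = standardize(sub)
    n_x = np.full(panel.n_sites, np.nan)
    n_x[keep] = _site_baseline(sub)

    rng = np.random.default_rng(seed)
    regions = gmap.arm_ids
    R = len(regions)
    y = np.full((R, n_bins), np.nan)
    var = np.full((R, n_bins), np.nan)
    base = np.full((R, n_bins), np.nan)
    n_pairs = np.zeros((R, n_bins), dtype=np.int64)

    arm_col = gmap.sites["arm"].to_numpy()
    cm_col = gmap.sites["pos_cm"].to_numpy()
    for ri, reg in enumerate(regions):
        idx = np.where((arm_col == reg) & keep)[0]
        if len(idx) < 2:
            continue
        cm = cm_col[idx]
        r2, _ = _r2_matrices(G[:, idx])
        iu, ju = np.triu_indices(len(idx), k=1)
        d = cm[ju] - cm[iu]
        inwin = (d >= lo) & (d < hi)
        iu, ju, d = iu[inwin], ju[inwin], d[inwin]
        vals = r2[iu, ju]
        b_of = np.floor((d - lo) / bin_width_cm).astype(int)
        bases = finite_sample_baseline(n_x[idx][iu], n_x[idx][ju])
        for b in range(n_bins):
            sel = np.where(b_of == b)[0]
            if len(sel) > pair_cap:
                sel = rng.choice(sel, size=pair_cap, replace=False)
            v = vals[sel]
            ok = ~np.isnan(v)
            v = v[ok]
            if v.size == 0:
                continue
            n_pairs[ri, b] = v.size
            y[ri, b] = v.mean()
            base[ri, b] = np.nanmean(bases[sel][ok])
            n_sites_b = len(np.unique(np.r_[iu[sel][ok], ju[sel][ok]]))
            multiplicity = max(1.0, 2.0 * v.size / max(1, n_sites_b))
            n_eff = max(1.0, v.size / multiplicity)
            var[ri, b] = (v.var(ddof=1) / n_eff) if v.size > 1 else np.nan

    mean_hap = float(np.nanmean(n_x))
    ld = BinnedLD(regions, edges, y, n_pairs, var, base, mean_hap, panel.ploidy_mode)
    if not ld.usable.any():
        raise ValueError("no region has >= 2 usable LD bins")
    return ld


@dataclass
class CCLDReport:
    """Cross-chromosome LD summary: per-chromosome-pair means of the
    baseline-corrected 4-point statistic, pooled t-test against zero."""

    pair_means: pd.DataFrame
    pooled_mean: float
    t_stat: float
    p_value: float
    significant: bool
    applicable: bool = True

    def to_tsv(self, path) -> None:
        self.pair_means.to_csv(path, sep="\t", index=False)

    def summary(self) -> str:
        if not self.applicable:
            return "CCLD test not applicable (single chromosome)"
        flag = "SIGNIFICANT" if self.significant else "not significant"
        return (f"CCLD pooled mean {self.pooled_mean:.3e}, "
                f"t = {self.t_stat:.3f}, p = {self.p_value:.4g} ({flag})")


def ccld_test(panel: GenotypePanel, gmap: GeneticMap,
              maf_min: float = DEFAULT_MAF_MIN,
              max_pairs_per_chrom_pair: int = 20_000,
              alpha: float = 0.05, seed: int = 0) -> CCLDReport:
    """Test for population structure via cross-chromosome LD.

    For sampled site pairs on different chromosomes the mean over distinct
    individual pairs of ``G_ix G_iy G_jx G_jy`` should equal the
    finite-sample term ``4/((N_x-1)(N_y-1))``; the baseline-corrected
    statistic is averaged per chromosome pair and a one-sample two-sided
    t-test across chromosome pairs checks the zero-mean hypothesis.
    """
    p = panel.allele_freq()
    calls = panel.site_call_counts()
    keep = (np.minimum(p, 1 - p) > maf_min) & (calls >= 2)
    sub = panel.drop_sites(keep)
    G = standardize(sub)
    n_x = _site_baseline(sub)
    chroms = gmap.sites["chrom"].to_numpy()[keep]
    uniq = np.unique(chroms)
    if len(uniq) < 2:
        warnings.warn("CCLD test requires >= 2 chromosomes; skipping")
        return CCLDReport(pd.DataFrame(), np.nan, np.nan, np.nan, False,
                          applicable=False)
    rng = np.random.default_rng(seed)
    rows = []
    for a_i in range(len(uniq)):
        for b_i in range(a_i + 1, len(uniq)):
            ca, cb = uniq[a_i], uniq[b_i]
            ia = np.where(chroms == ca)[0]
            ib = np.where(chroms == cb)[0]
            n_combo = len(ia) * len(ib)
            take = min(n_combo, max_pairs_per_chrom_pair)
            flat = rng.choice(n_combo, size=take, replace=False)
            xa, xb = ia[flat // len(ib)], ib[flat % len(ib)]
            r2, O = _r2_matrices_cross(G[:, xa], G[:, xb])
            stat = r2 - finite_sample_baseline(n_x[xa], n_x[xb])
            ok = ~np.isnan(stat)
            if ok.sum() == 0:
                continue
            rows.append((ca, cb, float(np.mean(stat[ok])), int(ok.sum())))
    pair_means = pd.DataFrame(rows, columns=["chrom_a", "chrom_b", "mean_stat",
                                             "n_site_pairs"])
    vals = pair_means["mean_stat"].to_numpy()
    t_stat, p_value = stats.ttest_1samp(vals, 0.0)
    return CCLDReport(pair_means, float(vals.mean()), float(t_stat),
                      float(p_value), bool(p_value < alpha))


def _r2_matrices_cross(Ga: np.ndarray, Gb: np.ndarray):
    """Elementwise R^2 between paired columns of two equally sized blocks."""
    oa, ob = ~np.isnan(Ga), ~np.isnan(Gb)
    Za, Zb = np.where(oa, Ga, 0.0), np.where(ob, Gb, 0.0)
    joint = oa & ob
    T = np.sum(Za * Zb * joint, axis=0)
    Q = np.sum((Za * Zb) ** 2 * joint, axis=0)
    O = joint.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = (T * T - Q) / (O * (O - 1.0))
    r2[O < 2] = np.nan
    return r2, O
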