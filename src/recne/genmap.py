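"""Genetic maps with chromosome-arm regions.

Chromosome arms are the unit of independence for everything downstream:
LD and IBD summaries are accumulated per arm, outlier filtering drops whole
arms, and bootstrap confidence bands resample arms with replacement.  The
default genome emulates the human autosomes: 39 arms (17 metacentric
chromosomes contributing two arms each, 5 acrocentric ones a single arm)
totaling 36.23 Morgans.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

# Approximate sex-averaged genetic lengths (cM) of the 22 human autosomes and
# the fraction of genetic length on the p arm.  Acrocentric chromosomes
# (13, 14, 15, 21, 22) are treated as a single region.  Values are rounded
# book numbers, rescaled below so the genome totals exactly 36.23 Morgans.
_CHROM_CM = {
    1: 286.0, 2: 269.0, 3: 223.0, 4: 214.0, 5: 204.0, 6: 192.0, 7: 187.0,
    8: 168.0, 9: 166.0, 10: 181.0, 11: 158.0, 12: 175.0, 13: 126.0,
    14: 119.0, 15: 141.0, 16: 134.0, 17: 128.0, 18: 117.0, 19: 107.0,
    20: 108.0, 21: 62.0, 22: 74.0,
}
_ACROCENTRIC = {13, 14, 15, 21, 22}
_P_FRACTION = {
    1: 0.43, 2: 0.38, 3: 0.46, 4: 0.26, 5: 0.25, 6: 0.36, 7: 0.37,
    8: 0.29, 9: 0.35, 10: 0.28, 11: 0.36, 12: 0.26, 16: 0.33, 17: 0.30,
    18: 0.23, 19: 0.45, 20: 0.42,
}
TOTAL_GENOME_MORGANS = 36.23
#: bp per cM used when synthesizing physical coordinates (1 cM/Mb).
BP_PER_CM = 1_000_000


def human_arm_table() -> pd.DataFrame:
    """39-arm table: arm id, chromosome, chromosome-local start/end in cM."""
    scale = TOTAL_GENOME_MORGANS * 100.0 / sum(_CHROM_CM.values())
    rows = []
    arm_id = 1
    for chrom, cm in _CHROM_CM.items():
        cm *= scale
        if chrom in _ACROCENTRIC:
            rows.append((arm_id, chrom, 0.0, cm))
            arm_id += 1
        else:
            split = cm * _P_FRACTION[chrom]
            rows.append((arm_id, chrom, 0.0, split))
            rows.append((arm_id + 1, chrom, split, cm))
            arm_id += 2
    return pd.DataFrame(rows, columns=["arm", "chrom", "start_cm", "end_cm"])


def uniform_arm_table(n_arms: int, arm_length_cm: float) -> pd.DataFrame:
    """Synthetic genome of ``n_arms`` equal arms, one arm per 'chromosome'
    pair (two arms per chromosome, odd leftover arm on its own chromosome)."""
    rows = []
    for i in range(n_arms):
        chrom = i // 2 + 1
        start = (i % 2) * arm_length_cm
        rows.append((i + 1, chrom, start, start + arm_length_cm))
    return pd.DataFrame(rows, columns=["arm", "chrom", "start_cm", "end_cm"])


def single_arm_table(n_chroms: int, arm_length_cm: float) -> pd.DataFrame:
    """Synthetic genome with one arm per chromosome — maximizes the number of
    chromosome pairs available to the cross-chromosome LD test."""
    return pd.DataFrame({
        "arm": np.arange(1, n_chroms + 1),
        "chrom": np.arange(1, n_chroms + 1),
        "start_cm": 0.0,
        "end_cm": arm_length_cm,
    })


@dataclass
class GeneticMap:
    """Per-site genetic coordinates plus the arm (region) table.

    ``sites``: columns chrom, arm, pos_bp, pos_cm (chromosome-local cM),
    ordered to match the site axis of the genotype panel they describe.
    ``arms``: columns arm, chrom, start_cm, end_cm.
    """

    sites: pd.DataFrame
    arms: pd.DataFrame

    def __post_init__(self):
        req = {"chrom", "arm", "pos_bp", "pos_cm"}
        if not req.issubset(self.sites.columns):
            raise ValueError(f"site table must have columns {sorted(req)}")
        for _, grp in self.sites.groupby("arm"):
            if not grp["pos_cm"].is_monotonic_increasing:
                raise ValueError("genetic positions must be non-decreasing within an arm")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def arm_ids(self) -> np.ndarray:
        return self.arms["arm"].to_numpy()

    def arm_lengths_morgans(self) -> pd.Series:
        """Genetic length of each arm in Morgans, indexed by arm id."""
        lengths = (self.arms["end_cm"] - self.arms["start_cm"]) / 100.0
        return pd.Series(lengths.to_numpy(), index=self.arms["arm"].to_numpy(), name="L_morgans")

    def interp_cm(self, chrom: int, bp) -> np.ndarray:
        """Interpolate chromosome-local cM positions from bp using this map's
        sites (linear, constant extrapolation at the ends)."""
        sub = self.sites[self.sites["chrom"] == chrom]
        if len(sub) < 2:
            raise ValueError(f"chromosome {chrom} has fewer than 2 mapped sites")
        return np.interp(np.asarray(bp, dtype=float), sub["pos_bp"].to_numpy(dtype=float),
                         sub["pos_cm"].to_numpy(dtype=float))

    def arm_of(self, chrom: int, cm: float) -> int | None:
        """Arm containing chromosome-local position ``cm`` (None if off-map)."""
        sub = self.arms[self.arms["chrom"] == chrom]
        for _, row in sub.iterrows():
            if row["start_cm"] <= cm < row["end_cm"] or (
                    cm == row["end_cm"] and row["end_cm"] == sub["end_cm"].max()):
                return int(row["arm"])
        return None

    def arm_boundaries(self, chrom: int) -> np.ndarray:
        """Interior arm boundaries (cM) of a chromosome (empty if single-arm)."""
        sub = self.arms[self.arms["chrom"] == chrom].sort_values("start_cm")
        return sub["start_cm"].to_numpy()[1:]

    def to_tsv(self, path) -> None:
        """PLINK .map-style TSV with an extra arm column:
        chrom, id, pos_cm, pos_bp, arm."""
        df = self.sites.copy()
        df.insert(1, "id", [f"snp{i}" for i in range(len(df))])
        df[["chrom", "id", "pos_cm", "pos_bp", "arm"]].to_csv(
            path, sep="\t", index=False, header=False)

    @classmethod
    def from_tsv(cls, path, arms: pd.DataFrame | None = None) -> "GeneticMap":
        """Read the map written by :meth:`to_tsv`.

        If no arm table is supplied, arm extents are taken to span the
        observed sites of each arm.
        """
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["chrom", "id", "pos_cm", "pos_bp", "arm"])
        sites = df[["chrom", "arm", "pos_bp", "pos_cm"]].copy()
        if arms is None:
            arms = (sites.groupby("arm")
                    .agg(chrom=("chrom", "first"), start_cm=("pos_cm", "min"),
                         end_cm=("pos_cm", "max"))
                    .reset_index())
        return cls(sites, arms)


def place_sites(arms: pd.DataFrame, sites_per_arm: int,
                rng: np.random.Generator) -> pd.DataFrame:
    """Scatter ``sites_per_arm`` sites uniformly (in cM) on each arm.

    Returns a site table with synthetic physical positions at 1 cM/Mb.
    """
    frames = []
    for _, row in arms.iterrows():
        cm = np.sort(rng.uniform(row["start_cm"], row["end_cm"], size=sites_per_arm))
        frames.append(pd.DataFrame({
            "chrom": int(row["chrom"]),
            "arm": int(row["arm"]),
            "pos_bp": np.round(cm * BP_PER_CM).astype(np.int64),
            "pos_cm": cm,
        }))
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["chrom", "pos_cm"], kind="stable").reset_index(drop=True)
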