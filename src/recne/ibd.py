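"""IBD segment lists and per-arm length-bin count histograms.

Segments are read from RefinedIBD/HapIBD-style tab-separated output
(detection itself is external); genetic coordinates are interpolated from
the genetic map when the file carries only physical positions.  Counts of
segments >= 2 cM per (arm, 0.5 cM length bin) are the observation vector of
the IBD-based likelihood: each count is modeled as Poisson with mean
``mu_b(N_e) * L_i * n_pairs``.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genmap import GeneticMap

DEFAULT_U_MIN_CM = 2.0
BIN_WIDTH_CM = 0.5


@dataclass(frozen=True)
class IBDSegment:
    id1: str
    hap1: int
    id2: str
    hap2: int
    chrom: int
    start_bp: int
    end_bp: int
    start_cm: float
    end_cm: float

    def __post_init__(self):
        if self.end_bp <= self.start_bp or self.end_cm <= self.start_cm:
            raise ValueError("segment end must exceed start")

    @property
    def length_cm(self) -> float:
        return self.end_cm - self.start_cm

    @property
    def midpoint_cm(self) -> float:
        return 0.5 * (self.start_cm + self.end_cm)


def read_ibd(path, gmap: GeneticMap, max_malformed_frac: float = 0.10) -> list[IBDSegment]:
    """Parse an .ibd TSV (plain or gzip).

    Expected columns: id1, hap1, id2, hap2, chrom, start_bp, end_bp,
    [score/length].  cM coordinates are interpolated from the map.  Segments
    spanning a centromere (arm boundary) are split at the boundary so that
    arms stay disjoint resampling units.  Unknown chromosomes are skipped
    with a warning; more than ``max_malformed_frac`` malformed lines is an
    error.
    """
    opener = gzip.open if str(path).endswith(".gz") else open
    segments: list[IBDSegment] = []
    n_lines = n_bad = 0
    known_chroms = set(gmap.sites["chrom"].unique())
    with opener(path, "rt") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            n_lines += 1
            parts = line.split("\t")
            if len(parts) < 7:
                parts = line.split()
            try:
                id1, hap1, id2, hap2 = parts[0], int(parts[1]), parts[2], int(parts[3])
                chrom, start_bp, end_bp = int(parts[4]), int(parts[5]), int(parts[6])
                if end_bp <= start_bp:
                    raise ValueError("end <= start")
            except (ValueError, IndexError):
                n_bad += 1
                continue
            if chrom not in known_chroms:
                warnings.warn(f"unknown chromosome {chrom} in IBD file; skipping line")
                continue
            start_cm, end_cm = gmap.interp_cm(chrom, [start_bp, end_bp])
            if end_cm <= start_cm:
                n_bad += 1
                continue
            for seg in _split_at_boundaries(id1, hap1, id2, hap2, chrom,
                                            start_bp, end_bp, start_cm, end_cm, gmap):
                segments.append(seg)
    if n_lines == 0:
        warnings.warn(f"empty IBD file: {path}")
    elif n_bad / n_lines > max_malformed_frac:
        raise ValueError(f"{n_bad}/{n_lines} malformed IBD lines in {path}")
    elif n_bad:
        warnings.warn(f"{n_bad}/{n_lines} malformed IBD lines skipped in {path}")
    return segments


def _split_at_boundaries(id1, hap1, id2, hap2, chrom, start_bp, end_bp,
                         start_cm, end_cm, gmap: GeneticMap):
    cuts = [b for b in gmap.arm_boundaries(chrom) if start_cm < b < end_cm]
    cm_points = [start_cm] + cuts + [end_cm]
    bp_points = np.interp(cm_points, [start_cm, end_cm], [start_bp, end_bp])
    out = []
    for k in range(len(cm_points) - 1):
        out.append(IBDSegment(id1, hap1, id2, hap2, chrom,
                              int(round(bp_points[k])), int(round(bp_points[k + 1])),
                              cm_points[k], cm_points[k + 1]))
    return out


@dataclass
class IBDHistogram:
    """Per-(arm, length-bin) IBD segment counts.

    ``counts`` is (region x bin) of nonnegative integers; ``lengths_morgans``
    holds each region's genetic length L_i; ``n_pairs`` is the number of
    analyzed haplotype pairs; ``dispersion`` (phi^2 per bin) is filled by the
    inference module.
    """

    regions: np.ndarray
    bin_edges_cm: np.ndarray
    counts: np.ndarray
    lengths_morgans: np.ndarray
    n_pairs: int
    dispersion: np.ndarray = field(default=None)

    def __post_init__(self):
        if np.any(self.counts < 0):
            raise ValueError("negative counts")
        if self.dispersion is None:
            self.dispersion = np.ones(self.n_bins)

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges_cm) - 1

    @property
    def bin_edges_morgans(self) -> np.ndarray:
        return self.bin_edges_cm / 100.0

    def subset(self, region_ids) -> "IBDHistogram":
        pos = {r: i for i, r in enumerate(self.regions)}
        idx = np.array([pos[r] for r in region_ids], dtype=int)
        return IBDHistogram(np.asarray(region_ids), self.bin_edges_cm,
                            self.counts[idx], self.lengths_morgans[idx],
                            self.n_pairs, self.dispersion)

    def to_tsv(self, path) -> None:
        rows = []
        for i, reg in enumerate(self.regions):
            for b in range(self.n_bins):
                rows.append((reg, self.bin_edges_cm[b], self.bin_edges_cm[b + 1],
                             int(self.counts[i, b]), self.lengths_morgans[i],
                             self.n_pairs))
        pd.DataFrame(rows, columns=["region", "bin_lo_cm", "bin_hi_cm", "count",
                                    "L_i_morgans", "n_pairs"]).to_csv(
            path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "IBDHistogram":
        df = pd.read_csv(path, sep="\t")
        regions = df["region"].unique()
        edges = np.unique(np.r_[df["bin_lo_cm"].to_numpy(), df["bin_hi_cm"].to_numpy()])
        n_bins = len(edges) - 1
        counts = np.zeros((len(regions), n_bins), dtype=np.int64)
        lengths = np.zeros(len(regions))
        for i, reg in enumerate(regions):
            sub = df[df["region"] == reg].sort_values("bin_lo_cm")
            counts[i] = sub["count"].to_numpy()
            lengths[i] = sub["L_i_morgans"].iloc[0]
        return cls(regions, edges, counts, lengths, int(df["n_pairs"].iloc[0]))


def haplotype_pair_count(n_individuals: int) -> int:
    """Cross-individual haplotype pairs for a diploid panel: both phases of
    each individual pair, self-pairs excluded -> 4 * C(n, 2)."""
    return 2 * n_individuals * (n_individuals - 1)


def build_ibd_histogram(segments: list[IBDSegment], gmap: GeneticMap,
                        u_min_cm: float = DEFAULT_U_MIN_CM,
                        n_pairs: int | None = None) -> IBDHistogram:
    """Bin segment lengths >= ``u_min_cm`` per arm in half-open 0.5 cM bins.

    A segment belongs to the arm containing its midpoint.  Bin edges run from
    ``u_min_cm`` to the longest observed segment.  ``n_pairs`` defaults to
    counting distinct individuals in the segment list (4 haplotype pairs per
    individual pair).
    """
    lengths = np.array([s.length_cm for s in segments])
    usable = lengths >= u_min_cm
    if not usable.any():
        raise ValueError(f"no IBD segments of length >= {u_min_cm} cM; "
                         "input unusable for inference")
    if n_pairs is None:
        ids = {s.id1 for s in segments} | {s.id2 for s in segments}
        n_pairs = haplotype_pair_count(len(ids))
    max_len = lengths[usable].max()
    n_bins = max(1, int(np.ceil((max_len - u_min_cm) / BIN_WIDTH_CM + 1e-9)))
    edges = u_min_cm + BIN_WIDTH_CM * np.arange(n_bins + 1)
    regions = gmap.arm_ids
    pos = {r: i for i, r in enumerate(regions)}
    counts = np.zeros((len(regions), n_bins), dtype=np.int64)
    for seg, length, ok in zip(segments, lengths, usable):
        if not ok:
            continue
        arm = gmap.arm_of(seg.chrom, seg.midpoint_cm)
        if arm is None:
            warnings.warn(f"segment midpoint off-map (chrom {seg.chrom}); skipping")
            continue
        b = min(int((length - u_min_cm) / BIN_WIDTH_CM), n_bins - 1)
        counts[pos[arm], b] += 1
    return IBDHistogram(regions, edges, counts,
                        gmap.arm_lengths_morgans().reindex(regions).to_numpy(),
                        int(n_pairs))


def write_ibd(segments: list[IBDSegment], path) -> None:
    """Write segments back to the RefinedIBD-style TSV layout."""
    with open(path, "w") as fh:
        for s in segments:
            fh.write(f"{s.id1}\t{s.hap1}\t{s.id2}\t{s.hap2}\t{s.chrom}\t"
                     f"{s.start_bp}\t{s.end_bp}\t{s.length_cm:.6f}\n")
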