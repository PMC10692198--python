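"""Genotype panel container and PLINK/VCF readers.

Genotypes are stored as a float matrix (samples x sites) of counted-allele
dosages in {0, 1, 2} with NaN for missing.  Pseudo-haploid panels (one
sequencing allele sampled per site, standard for low-coverage ancient DNA)
store the sampled allele doubled, so only {0, 2} occur and no heterozygous
call is possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class GenotypePanel:
    genotypes: np.ndarray
    ploidy_mode: str = "diploid"  # "diploid" | "pseudo_haploid"
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        g = np.asarray(self.genotypes, dtype=float)
        if g.ndim != 2:
            raise ValueError("genotypes must be a 2-d (samples x sites) matrix")
        ok = np.isnan(g) | np.isin(g, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("genotype entries must be in {0,1,2} or NaN")
        if self.ploidy_mode not in ("diploid", "pseudo_haploid"):
            raise ValueError(f"unknown ploidy_mode {self.ploidy_mode!r}")
        if self.ploidy_mode == "pseudo_haploid" and np.nansum(g == 1.0) > 0:
            raise ValueError("pseudo-haploid panel contains heterozygous calls")
        self.genotypes = g
        if not self.sample_ids:
            self.sample_ids = [f"sample{i}" for i in range(g.shape[0])]
        elif len(self.sample_ids) != g.shape[0]:
            raise ValueError("sample_ids length mismatch")

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[1]

    @property
    def n_haplotypes(self) -> int:
        """Effective haplotypes per site: one per sample for pseudo-haploid
        data (a single allele was observed), two for diploid."""
        return self.n_samples if self.ploidy_mode == "pseudo_haploid" else 2 * self.n_samples

    def allele_freq(self) -> np.ndarray:
        """Counted-allele frequency per site from non-missing entries."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.genotypes, axis=0) / 2.0

    def site_call_counts(self) -> np.ndarray:
        return np.sum(~np.isnan(self.genotypes), axis=0)

    def drop_sites(self, keep_mask: np.ndarray) -> "GenotypePanel":
        return GenotypePanel(self.genotypes[:, keep_mask], self.ploidy_mode,
                             list(self.sample_ids))


# ---------------------------------------------------------------- PLINK I/O
# 2-bit codes in a .bed byte, sample-within-byte little-endian:
# 00 -> 2 copies of A1 (counted allele), 10 -> 1 copy, 11 -> 0, 01 -> missing.
_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # SNP-major
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])


def write_plink(panel: GenotypePanel, prefix: str, map_df=None) -> None:
    """Write .bed/.bim/.fam; the counted allele is written as A1."""
    g = panel.genotypes
    n, m = g.shape
    codes = np.full(g.shape, 1, dtype=np.uint8)  # missing
    codes[g == 2.0] = 0
    codes[g == 1.0] = 2
    codes[g == 0.0] = 3
    n_bytes = (n + 3) // 4
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        padded = np.zeros((m, n_bytes * 4), dtype=np.uint8)
        padded[:, :n] = codes.T
        packed = (padded[:, 0::4] | (padded[:, 1::4] << 2)
                  | (padded[:, 2::4] << 4) | (padded[:, 3::4] << 6))
        fh.write(packed.astype(np.uint8).tobytes())
    with open(prefix + ".fam", "w") as fh:
        for sid in panel.sample_ids:
            fh.write(f"{sid} {sid} 0 0 0 -9\n")
    with open(prefix + ".bim", "w") as fh:
        for j in range(m):
            if map_df is not None:
                row = map_df.iloc[j]
                fh.write(f"{int(row['chrom'])} snp{j} {row['pos_cm']:.6f} "
                         f"{int(row['pos_bp'])} A G\n")
            else:
                fh.write(f"1 snp{j} 0 {j + 1} A G\n")


def read_plink(prefix: str, ploidy_mode: str = "diploid") -> tuple[GenotypePanel, "np.ndarray"]:
    """Read .bed/.bim/.fam; returns (panel, bim records as structured array)."""
    import pandas as pd

    fam = pd.read_csv(prefix + ".fam", sep=r"\s+", header=None)
    bim = pd.read_csv(prefix + ".bim", sep=r"\s+", header=None,
                      names=["chrom", "id", "pos_cm", "pos_bp", "a1", "a2"])
    n, m = len(fam), len(bim)
    n_bytes = (n + 3) // 4
    with open(prefix + ".bed", "rb") as fh:
        magic = fh.read(3)
        if magic != _BED_MAGIC:
            raise ValueError("not a SNP-major PLINK .bed file")
        raw = np.frombuffer(fh.read(), dtype=np.uint8)
    if raw.size != m * n_bytes:
        raise ValueError("bed size inconsistent with bim/fam")
    raw = raw.reshape(m, n_bytes)
    codes = np.empty((m, n_bytes * 4), dtype=np.uint8)
    codes[:, 0::4] = raw & 3
    codes[:, 1::4] = (raw >> 2) & 3
    codes[:, 2::4] = (raw >> 4) & 3
    codes[:, 3::4] = (raw >> 6) & 3
    g = _CODE_TO_DOSAGE[codes[:, :n]].T
    panel = GenotypePanel(g, ploidy_mode, [str(s) for s in fam[1]])
    return panel, bim


def read_vcf(path: str, ploidy_mode: str = "diploid") -> tuple[GenotypePanel, "object"]:
    """Read genotypes from a VCF via cyvcf2; returns (panel, site table)."""
    import pandas as pd
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    rows, columns = [], []
    for var in vcf:
        # gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        gt = var.gt_types.astype(float)
        dosage = np.where(gt == 0, 0.0, np.where(gt == 1, 1.0,
                          np.where(gt == 3, 2.0, np.nan)))
        columns.append(dosage)
        rows.append((var.CHROM, var.POS))
    g = np.column_stack(columns) if columns else np.empty((len(samples), 0))
    sites = pd.DataFrame(rows, columns=["chrom", "pos_bp"])
    return GenotypePanel(g, ploidy_mode, samples), sites
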