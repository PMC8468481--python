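"""Shared in-memory containers for genotype and phenotype data.

Dosages are minor-allele counts in {0, 1, 2} stored as floats, with
``numpy.nan`` as the missing sentinel (out-of-band; QC never imputes it).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: required columns of the SNP metadata frame
SNP_COLUMNS = ["snp", "chrom", "pos", "a1", "a2"]
#: required columns of the sample metadata frame
SAMPLE_COLUMNS = ["fid", "iid", "sex"]


@dataclass
class GenotypeMatrix:
    """Samples x SNPs allele-dosage matrix with metadata.

    Parameters
    ----------
    dosage
        ``(n_samples, n_snps)`` float array of minor-allele counts; ``nan``
        marks a missing call.
    snps
        Per-SNP metadata with columns ``snp, chrom, pos, a1, a2`` (a1 is the
        minor/counted allele, positions 1-based as in bim/VCF).
    samples
        Per-sample metadata with columns ``fid, iid, sex`` (sex: 1 male,
        2 female, 0 unknown -- PLINK convention).
    """

    dosage: np.ndarray
    snps: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be 2-D (samples x SNPs)")
        if len(self.snps) != self.dosage.shape[1]:
            raise ValueError(
                f"SNP metadata rows ({len(self.snps)}) != dosage columns "
                f"({self.dosage.shape[1]})"
            )
        if len(self.samples) != self.dosage.shape[0]:
            raise ValueError(
                f"sample metadata rows ({len(self.samples)}) != dosage rows "
                f"({self.dosage.shape[0]})"
            )
        missing = [c for c in SNP_COLUMNS if c not in self.snps.columns]
        if missing:
            raise ValueError(f"snps frame missing columns {missing}")
        missing = [c for c in SAMPLE_COLUMNS if c not in self.samples.columns]
        if missing:
            raise ValueError(f"samples frame missing columns {missing}")
        self.snps = self.snps.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    @property
    def snp_ids(self) -> np.ndarray:
        return self.snps["snp"].to_numpy()

    @property
    def sample_ids(self) -> np.ndarray:
        return self.samples["iid"].to_numpy()

    def snp_index(self, snp_id: str) -> int:
        idx = np.flatnonzero(self.snp_ids == snp_id)
        if idx.size == 0:
            raise KeyError(f"unknown SNP id {snp_id!r}")
        return int(idx[0])

    def subset(self, sample_idx=None, snp_idx=None) -> "GenotypeMatrix":
        """Return a copy restricted to the given sample/SNP index arrays."""
        sample_idx = (
            np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        )
        snp_idx = np.arange(self.n_snps) if snp_idx is None else np.asarray(snp_idx)
        return GenotypeMatrix(
            dosage=self.dosage[np.ix_(sample_idx, snp_idx)].copy(),
            snps=self.snps.iloc[snp_idx].copy(),
            samples=self.samples.iloc[sample_idx].copy(),
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosage.copy(), self.snps.copy(), self.samples.copy())

    def missing_rate_per_snp(self) -> np.ndarray:
        return np.isnan(self.dosage).mean(axis=0)

    def missing_rate_per_sample(self) -> np.ndarray:
        return np.isnan(self.dosage).mean(axis=1)


@dataclass
class AssocRecord:
    """One SNP x phenotype association test result."""

    snp: str
    chrom: int
    pos: int
    phenotype: str
    model: str  # "additive" | "dominant"
    adjusted: bool  # True when the mediator was covaried
    beta: float
    se: float
    p: float
    n: int
    note: str = ""

    def as_dict(self) -> dict:
        return {
            "snp": self.snp,
            "chrom": self.chrom,
            "pos": self.pos,
            "phenotype": self.phenotype,
            "model": self.model,
            "adjusted": self.adjusted,
            "beta": self.beta,
            "se": self.se,
            "p": self.p,
            "n": self.n,
            "note": self.note,
        }


def assoc_table(records) -> pd.DataFrame:
    """Collect AssocRecords into a tidy DataFrame."""
    return pd.DataFrame([r.as_dict() for r in records])
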