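"""PLINK 1 binary (bed/bim/fam) reading and writing.

SNP-major bed layout: a 3-byte magic ``6c 1b 01`` followed by
``ceil(n_samples / 4)`` bytes per variant, two bits per sample starting at
the least-significant pair.  Two-bit codes: ``00`` = homozygous A1, ``01`` =
missing, ``10`` = heterozygous, ``11`` = homozygous A2.  We store dosages as
counts of A1, so A1 plays the minor-allele role.
"""
from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix

_MAGIC = bytes([0x6C, 0x1B, 0x01])

# code -> A1 dosage (nan = missing)
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])


def _decode_table() -> np.ndarray:
    """(256, 4) lookup: byte -> four dosages (sample-within-byte order)."""
    table = np.empty((256, 4))
    for byte in range(256):
        for k in range(4):
            table[byte, k] = _CODE_TO_DOSAGE[(byte >> (2 * k)) & 0b11]
    return table


_DECODE = _decode_table()


def read_plink(prefix: str) -> GenotypeMatrix:
    """Read ``prefix``.bed/.bim/.fam into a GenotypeMatrix."""
    bim = pd.read_csv(
        prefix + ".bim",
        sep=r"\s+",
        header=None,
        names=["chrom", "snp", "cm", "pos", "a1", "a2"],
        dtype={"chrom": int, "snp": str, "pos": int, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        prefix + ".fam",
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "phenotype"],
        dtype={"fid": str, "iid": str},
    )
    n, m = len(fam), len(bim)
    bytes_per_snp = (n + 3) // 4
    with open(prefix + ".bed", "rb") as fh:
        magic = fh.read(3)
        if magic != _MAGIC:
            raise ValueError(f"{prefix}.bed: bad magic bytes {magic!r}")
        raw = np.frombuffer(fh.read(), dtype=np.uint8)
    if raw.size != m * bytes_per_snp:
        raise ValueError(
            f"{prefix}.bed: expected {m * bytes_per_snp} genotype bytes, "
            f"found {raw.size}"
        )
    # decode to (m, 4 * bytes_per_snp) then truncate padding samples
    decoded = _DECODE[raw.reshape(m, bytes_per_snp)].reshape(m, -1)[:, :n]
    snps = bim[["snp", "chrom", "pos", "a1", "a2"]].copy()
    samples = fam[["fid", "iid", "sex"]].copy()
    return GenotypeMatrix(dosage=decoded.T.copy(), snps=snps, samples=samples)


def write_plink(g: GenotypeMatrix, prefix: str) -> None:
    """Write a GenotypeMatrix as ``prefix``.bed/.bim/.fam."""
    os.makedirs(os.path.dirname(os.path.abspath(prefix)), exist_ok=True)
    n, m = g.n_samples, g.n_snps
    dosage = g.dosage
    if np.nanmax(dosage, initial=0) > 2 or np.nanmin(dosage, initial=0) < 0:
        raise ValueError("dosages must lie in [0, 2]")

    codes = np.full((m, n), 0b01, dtype=np.uint8)  # missing by default
    dt = dosage.T
    codes[dt == 2] = 0b00
    codes[dt == 1] = 0b10
    codes[dt == 0] = 0b11

    bytes_per_snp = (n + 3) // 4
    padded = np.full((m, bytes_per_snp * 4), 0b01, dtype=np.uint8)
    padded[:, :n] = codes
    packed = (
        padded[:, 0::4]
        | (padded[:, 1::4] << 2)
        | (padded[:, 2::4] << 4)
        | (padded[:, 3::4] << 6)
    )
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_MAGIC)
        fh.write(packed.tobytes())

    bim = pd.DataFrame(
        {
            "chrom": g.snps["chrom"],
            "snp": g.snps["snp"],
            "cm": 0,
            "pos": g.snps["pos"],
            "a1": g.snps["a1"],
            "a2": g.snps["a2"],
        }
    )
    bim.to_csv(prefix + ".bim", sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {
            "fid": g.samples["fid"],
            "iid": g.samples["iid"],
            "father": 0,
            "mother": 0,
            "sex": g.samples["sex"],
            "phenotype": -9,
        }
    )
    fam.to_csv(prefix + ".fam", sep="\t", header=False, index=False)
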