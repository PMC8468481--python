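"""Effective number of independent tests from the SNP correlation spectrum.

The effective count is the smallest number of top eigenvalues of the SNP
dosage correlation matrix whose sum reaches a fixed fraction C (default
0.995) of the total — the simpleM construction — and feeds a Bonferroni
threshold of alpha / (Meff * number of phenotypes).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix


@dataclass
class EffectiveTests:
    M: int
    meff: int
    C: float
    eigenvalues: np.ndarray


def snp_correlation_matrix(g: GenotypeMatrix | np.ndarray) -> np.ndarray:
    """Pairwise-complete Pearson correlations of SNP dosages."""
    dosage = g.dosage if isinstance(g, GenotypeMatrix) else np.asarray(g, dtype=float)
    if dosage.shape[1] < 2:
        raise ValueError("need at least 2 SNPs")
    sd = np.nanstd(dosage, axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = (
            g.snp_ids[dead].tolist() if isinstance(g, GenotypeMatrix) else dead.tolist()
        )
        raise ValueError(f"zero-variance SNPs make correlations undefined: {names}")
    corr = pd.DataFrame(dosage).corr().to_numpy()
    np.fill_diagonal(corr, 1.0)
    return corr


def meff_gao(corr: np.ndarray, C: float = 0.995) -> EffectiveTests:
    """Smallest j with (sum of j largest eigenvalues) / (sum of all) >= C."""
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(corr, corr.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    if not 0 < C <= 1:
        raise ValueError("C must be in (0, 1]")
    eig = np.linalg.eigvalsh(corr)[::-1]
    eig = np.clip(eig, 0.0, None)  # absorb numerical negatives
    total = eig.sum()
    frac = np.cumsum(eig) / total
    meff = int(np.searchsorted(frac, C - 1e-12) + 1)
    return EffectiveTests(M=corr.shape[0], meff=meff, C=C, eigenvalues=eig)


def bonferroni_threshold(meff: int, n_phenotypes: int, alpha: float = 0.05) -> float:
    """alpha / (Meff * number of phenotype models)."""
    if meff < 1 or n_phenotypes < 1:
        raise ValueError("counts must be positive")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return alpha / (meff * n_phenotypes)
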