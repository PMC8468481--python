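"""Analytic power for an additive per-allele effect on a continuous trait.

The locus explains v = 2 * maf * (1 - maf) * beta^2 of the outcome variance
sd_y^2; the 1-df Wald test has noncentrality lambda = n * R^2 / (1 - R^2)
with R^2 = v / sd_y^2, and two-sided power
P(Z > z_{1-a/2} - sqrt(lambda)) + P(Z < -z_{1-a/2} - sqrt(lambda)).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm


@dataclass
class PowerQuery:
    n: int = 795
    maf_grid: np.ndarray = field(
        default_factory=lambda: np.round(np.arange(0.01, 0.501, 0.01), 10)
    )
    betas: tuple[float, ...] = (0.08, 1.62)
    sd_y: float = 1.0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        grid = np.asarray(self.maf_grid, dtype=float)
        if (grid <= 0).any() or (grid > 0.5).any():
            raise ValueError("maf grid must lie in (0, 0.5]")
        if self.sd_y <= 0:
            raise ValueError("sd_y must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def power_additive(n: int, maf: float, beta: float, sd_y: float, alpha: float = 0.05) -> float:
    """Two-sided normal-approximation power for one (maf, beta) setting."""
    v = 2.0 * maf * (1.0 - maf) * beta * beta
    r2 = v / (sd_y * sd_y)
    if r2 >= 1:
        warnings.warn("locus variance exceeds the outcome variance; power = 1")
        return 1.0
    lam = n * r2 / (1.0 - r2)
    z = norm.isf(alpha / 2.0)
    root = np.sqrt(lam)
    return float(norm.sf(z - root) + norm.cdf(-z - root))


def power_range(query: PowerQuery) -> tuple[float, float]:
    """(min, max) power over the MAF grid x effect-size set."""
    vals = [
        power_additive(query.n, m, b, query.sd_y, query.alpha)
        for m in np.asarray(query.maf_grid, dtype=float)
        for b in query.betas
    ]
    return float(min(vals)), float(max(vals))


def power_percent(power: float, cap: float = 99.99) -> float:
    """Power as a percentage to 2 decimals, capped for display."""
    return float(min(round(100.0 * power, 2), cap))
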