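"""Scale scoring, reliability, residualization, correlation, discretization.

Scale scores are means over answered items (prorated scoring).  Residuals
are OLS residuals on confounders, standardized to mean 0 / SD 1, as used
for phenotype-phenotype correlation screening.  Tercile discretization
feeds the Bayesian-network stage.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ScaleDefinition:
    """A questionnaire scale: item columns and their admissible range."""

    name: str
    items: list[str]
    response_range: tuple[float, float]
    subscales: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for sub, its in self.subscales.items():
            if seen & set(its):
                raise ValueError(f"subscale {sub!r} overlaps another subscale")
            seen |= set(its)
            if not set(its) <= set(self.items):
                raise ValueError(f"subscale {sub!r} has items outside the scale")


@dataclass
class ResidualSpec:
    target: str
    covariates: list[str]

    def __post_init__(self) -> None:
        if self.target in self.covariates:
            raise ValueError("target must not appear among its covariates")


def score_scale(items: pd.DataFrame, scale: ScaleDefinition) -> pd.Series:
    """Mean over answered items; all-missing rows score missing."""
    lo, hi = scale.response_range
    block = items[scale.items]
    bad = ((block < lo) | (block > hi)).any(axis=None)
    if bool(bad):
        raise ValueError(f"responses outside [{lo}, {hi}] in scale {scale.name!r}")
    return block.mean(axis=1, skipna=True).rename(scale.name)


def cronbach_alpha(items: pd.DataFrame | np.ndarray) -> float:
    """Cronbach's alpha, complete-case.

    alpha = k/(k-1) * (1 - sum of item variances / total-score variance).
    """
    x = pd.DataFrame(items).dropna().to_numpy(dtype=float)
    k = x.shape[1]
    if k < 2 or x.shape[0] < 2:
        raise ValueError("need >= 2 items and >= 2 complete samples")
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var == 0:
        return np.nan
    item_var = x.var(axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_var / total_var))


def residualize(frame: pd.DataFrame, spec: ResidualSpec) -> pd.Series:
    """Standardized OLS residuals of the target on covariates + intercept."""
    cols = [spec.target] + list(spec.covariates)
    data = frame[cols].dropna()
    y = data[spec.target].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(data))] + [data[c].to_numpy(dtype=float) for c in spec.covariates])
    if len(data) <= X.shape[1]:
        raise ValueError("more covariates than observations")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError("collinear covariates in residualization")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sd = resid.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate residuals (zero variance)")
    return pd.Series(resid / sd, index=data.index, name=f"{spec.target}_resid")


def correlation_screen(
    residuals: pd.DataFrame | pd.Series, outcomes: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Pearson r and two-sided p for every residual x outcome pair.

    P-values use the exact t transform with n-2 degrees of freedom;
    pairwise-complete observations.
    """
    if isinstance(residuals, pd.Series):
        residuals = residuals.to_frame()
    rows = []
    for rcol in residuals.columns:
        for ocol in outcomes.columns:
            pair = pd.concat([residuals[rcol], outcomes[ocol]], axis=1).dropna()
            n = len(pair)
            if n < 3:
                raise ValueError(f"pair ({rcol}, {ocol}): fewer than 3 complete cases")
            x, y = pair.iloc[:, 0], pair.iloc[:, 1]
            if x.std() == 0 or y.std() == 0:
                rows.append({"mediator": rcol, "outcome": ocol, "n": n, "r": np.nan, "p": np.nan, "significant": False})
                continue
            r, p = stats.pearsonr(x, y)
            rows.append(
                {"mediator": rcol, "outcome": ocol, "n": n, "r": float(r), "p": float(p), "significant": bool(p <= alpha)}
            )
    return pd.DataFrame(rows)


def discretize_terciles(x, name: str = "x") -> np.ndarray:
    """Three-level coding (0 low, 1 mid, 2 high) by empirical terciles.

    Ties at a boundary all receive the lower category (left-closed cut),
    making the labels deterministic and order-independent.
    """
    arr = np.asarray(x, dtype=float)
    if np.isnan(arr).any():
        raise ValueError(f"{name}: missing values cannot be discretized")
    if np.unique(arr).size < 3:
        raise ValueError(f"{name}: fewer than 3 distinct values")
    q1, q2 = np.quantile(arr, [1.0 / 3.0, 2.0 / 3.0])
    out = np.full(arr.shape, 2, dtype=int)
    out[arr <= q2] = 1
    out[arr <= q1] = 0
    return out
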