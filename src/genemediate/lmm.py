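"""Kinship-corrected linear mixed model association scans.

The model per phenotype is ``y = W a + u + e`` with ``u ~ N(0, sg2 K)`` and
``e ~ N(0, se2 I)``.  A single eigendecomposition of the kinship matrix K
rotates the problem to independent observations, after which the restricted
likelihood is profiled over the variance ratio delta = se2/sg2 on a log
grid with bounded local refinement.  Each SNP is then tested by GLS at the
null-model delta (population parameters previously determined), with a
1-df Wald chi-square p-value.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .containers import AssocRecord, GenotypeMatrix, assoc_table

_DELTA_GRID = np.logspace(-5, 5, 50)


@dataclass
class LMMModelSpec:
    """One phenotype's scan configuration."""

    outcome: str
    covariates: list[str] = field(default_factory=lambda: ["sex", "age"])
    coding: str = "additive"  # "additive" | "dominant"
    mediator: str | None = None  # extra covariate in secondary analyses

    def all_covariates(self) -> list[str]:
        cov = list(self.covariates)
        if self.mediator is not None:
            cov.append(self.mediator)
        return cov


@dataclass
class LMMFit:
    """Null-model REML fit plus the cached spectral rotation."""

    sigma_g2: float
    sigma_e2: float
    delta: float
    loglik: float
    alpha: np.ndarray
    alpha_cov: np.ndarray
    s: np.ndarray  # eigenvalues of K
    U: np.ndarray  # eigenvectors of K
    Uy: np.ndarray
    UW: np.ndarray
    n: int


def grm(g: GenotypeMatrix, exclude_chromosome: int | None = None) -> np.ndarray:
    """Genomic relationship matrix K = Z Z' / M from standardized dosages.

    Missing dosages are mean-imputed per SNP before standardization;
    monomorphic SNPs are dropped.  ``exclude_chromosome`` implements the
    leave-one-chromosome-out convention.
    """
    mask = np.ones(g.n_snps, dtype=bool)
    if exclude_chromosome is not None:
        mask &= (g.snps["chrom"] != exclude_chromosome).to_numpy()
    d = g.dosage[:, mask]
    if d.shape[1] == 0:
        raise ValueError("no SNPs remain for kinship estimation")
    mu = np.nanmean(d, axis=0)
    d = np.where(np.isnan(d), mu[None, :], d)
    sd = d.std(axis=0)
    poly = sd > 0
    z = (d[:, poly] - d[:, poly].mean(axis=0)) / sd[poly]
    if z.shape[1] == 0:
        raise ValueError("all kinship SNPs are monomorphic")
    return (z @ z.T) / z.shape[1]


def _reml_parts(delta: float, s: np.ndarray, Uy: np.ndarray, UW: np.ndarray):
    d = s + delta
    Wd = UW / d[:, None]
    WtDW = Wd.T @ UW
    alpha = np.linalg.solve(WtDW, Wd.T @ Uy)
    r = Uy - UW @ alpha
    rss = float((r * r / d).sum())
    return d, WtDW, alpha, rss


def reml_loglik(delta: float, s: np.ndarray, Uy: np.ndarray, UW: np.ndarray) -> float:
    """Profile restricted log-likelihood at a given variance ratio delta."""
    n, q = UW.shape
    d, WtDW, _, rss = _reml_parts(delta, s, Uy, UW)
    sg2 = rss / (n - q)
    if sg2 <= 0:
        return -np.inf
    _, logdet_wtdw = np.linalg.slogdet(WtDW)
    _, logdet_wtw = np.linalg.slogdet(UW.T @ UW)
    return -0.5 * (
        (n - q) * (np.log(2 * np.pi * sg2) + 1.0)
        + np.log(d).sum()
        + logdet_wtdw
        - logdet_wtw
    )


def fit_null_lmm(y: np.ndarray, W: np.ndarray, K: np.ndarray) -> LMMFit:
    """REML fit of the variance components via the spectral trick."""
    y = np.asarray(y, dtype=float)
    W = np.asarray(W, dtype=float)
    n = y.size
    if W.shape[0] != n or K.shape != (n, n):
        raise ValueError("inconsistent dimensions")
    if np.linalg.matrix_rank(W) < W.shape[1]:
        raise ValueError("fixed-effect design is rank deficient")
    if y.std() == 0:
        raise ValueError("degenerate outcome with zero variance")
    if not np.allclose(K, K.T, atol=1e-8):
        raise ValueError("kinship matrix must be symmetric")
    s, U = np.linalg.eigh(K)
    if s.min() < -1e-6:
        raise ValueError("kinship matrix is not PSD within tolerance")
    s = np.clip(s, 0.0, None)
    Uy = U.T @ y
    UW = U.T @ W

    lls = np.array([reml_loglik(dl, s, Uy, UW) for dl in _DELTA_GRID])
    best = int(np.argmax(lls))
    lo = _DELTA_GRID[max(best - 1, 0)]
    hi = _DELTA_GRID[min(best + 1, len(_DELTA_GRID) - 1)]
    res = optimize.minimize_scalar(
        lambda t: -reml_loglik(np.exp(t), s, Uy, UW),
        bounds=(np.log(lo), np.log(hi)),
        method="bounded",
        options={"xatol": 1e-6},
    )
    delta = float(np.exp(res.x))
    ll = -float(res.fun)

    d, WtDW, alpha, rss = _reml_parts(delta, s, Uy, UW)
    q = W.shape[1]
    sg2 = rss / (n - q)
    return LMMFit(
        sigma_g2=sg2,
        sigma_e2=sg2 * delta,
        delta=delta,
        loglik=ll,
        alpha=alpha,
        alpha_cov=sg2 * np.linalg.inv(WtDW),
        s=s,
        U=U,
        Uy=Uy,
        UW=UW,
        n=n,
    )


def snp_test(
    fit: LMMFit,
    snp_dosages: np.ndarray,
    coding: str = "additive",
    meta: dict | None = None,
) -> AssocRecord:
    """Wald test of one SNP appended to the null fixed effects.

    Missing dosages are mean-imputed; the residual scale is re-estimated at
    the null delta so that in the K = I limit the result matches OLS with a
    normal reference exactly.
    """
    meta = meta or {}
    x = np.asarray(snp_dosages, dtype=float).copy()
    if coding == "dominant":
        x = np.where(np.isnan(x), np.nan, (x > 0).astype(float))
    elif coding != "additive":
        raise ValueError(f"unknown genetic coding {coding!r}")
    mu = np.nanmean(x)
    x = np.where(np.isnan(x), mu, x)
    base = dict(
        snp=meta.get("snp", "snp"),
        chrom=meta.get("chrom", 0),
        pos=meta.get("pos", 0),
        phenotype=meta.get("phenotype", "y"),
        model=coding,
        adjusted=meta.get("adjusted", False),
        n=fit.n,
    )
    if np.std(x) == 0:
        return AssocRecord(beta=np.nan, se=np.nan, p=np.nan, note="monomorphic", **base)

    Ux = fit.U.T @ x
    X = np.column_stack([fit.UW, Ux])
    d = fit.s + fit.delta
    Xd = X / d[:, None]
    XtDX = Xd.T @ X
    if np.linalg.cond(XtDX) > 1e12:
        return AssocRecord(beta=np.nan, se=np.nan, p=np.nan, note="collinear", **base)
    XtDy = Xd.T @ fit.Uy
    beta = np.linalg.solve(XtDX, XtDy)
    r = fit.Uy - X @ beta
    rss = float((r * r / d).sum())
    q = X.shape[1]
    sg2 = rss / (fit.n - q)
    cov = sg2 * np.linalg.inv(XtDX)
    b, se = float(beta[-1]), float(np.sqrt(cov[-1, -1]))
    wald = (b / se) ** 2
    p = float(stats.chi2.sf(wald, df=1))
    return AssocRecord(beta=b, se=se, p=p, **base)


def scan(
    g: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    specs: list[LMMModelSpec],
    K: np.ndarray | None = None,
    loco: bool = False,
    snp_idx=None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Full SNP x phenotype association grid.

    ``phenotypes`` is indexed by sample iid and aligned to ``g``; with
    ``loco=True`` the kinship matrix is rebuilt per tested chromosome,
    excluding it.  Per-model errors (e.g. a missing covariate) are recorded
    as error rows while the other models proceed.
    """
    phen = phenotypes.loc[g.sample_ids]
    snp_idx = np.arange(g.n_snps) if snp_idx is None else np.asarray(snp_idx)
    test_chroms = pd.unique(g.snps["chrom"].iloc[snp_idx])
    kinships: dict = {}
    for chrom in test_chroms:
        kinships[chrom] = grm(g, exclude_chromosome=chrom) if loco or K is None else K

    records = []
    for spec in specs:
        cols = [spec.outcome] + spec.all_covariates()
        missing_cols = [c for c in cols if c not in phen.columns]
        if missing_cols:
            records.append(
                AssocRecord(
                    snp="*",
                    chrom=0,
                    pos=0,
                    phenotype=spec.outcome,
                    model=spec.coding,
                    adjusted=spec.mediator is not None,
                    beta=np.nan,
                    se=np.nan,
                    p=np.nan,
                    n=0,
                    note=f"missing columns: {missing_cols}",
                )
            )
            continue
        sub = phen[cols].dropna()
        rows = np.flatnonzero(pd.Index(g.sample_ids).isin(sub.index))
        y = sub[spec.outcome].to_numpy(dtype=float)
        W = np.column_stack(
            [np.ones(len(sub))] + [sub[c].to_numpy(dtype=float) for c in spec.all_covariates()]
        )
        fits = {}
        for chrom in test_chroms:
            Ksub = kinships[chrom][np.ix_(rows, rows)]
            fits[chrom] = fit_null_lmm(y, W, Ksub)
        for j in snp_idx:
            chrom = int(g.snps["chrom"].iloc[j])
            rec = snp_test(
                fits[chrom],
                g.dosage[np.ix_(rows, [j])][:, 0],
                coding=spec.coding,
                meta={
                    "snp": g.snps["snp"].iloc[j],
                    "chrom": chrom,
                    "pos": int(g.snps["pos"].iloc[j]),
                    "phenotype": spec.outcome,
                    "adjusted": spec.mediator is not None,
                },
            )
            records.append(rec)
    table = assoc_table(records)
    table["significant"] = table["p"] <= alpha
    return table


def manhattan_table(assoc: pd.DataFrame) -> pd.DataFrame:
    """Chromosome / position / -log10 p export for plotting."""
    out = assoc[["snp", "chrom", "pos", "phenotype", "p"]].copy()
    with np.errstate(divide="ignore"):
        out["neg_log10_p"] = -np.log10(out["p"])
    return out
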