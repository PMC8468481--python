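"""Mediation screening, genome PCs, and the path-model SEM.

The path model is a recursive system: the mediator is regressed on the
carrier-coded SNP plus confounders; each outcome is regressed on the
mediator, the SNP, the confounders, and any genome principal components
selected for it.  Coefficients are maximum-likelihood (equation-wise OLS
is exact ML for a recursive system whose freed residual covariances span
the outcome block; a numerical polish of the normal-theory discrepancy is
applied whenever the model is over-identified).  Coefficient covariance is
the robust sandwich from stacked per-observation moment conditions, and
indirect effects a*b carry delta-method standard errors, standardized by
the model-implied outcome SD.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .containers import GenotypeMatrix


# ----------------------------------------------------------------------
# screening and coding
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class MediationCandidate:
    snp: str
    mediator: str
    outcome: str
    mediator_outcome_p: float
    snp_mediator_p: float
    snp_outcome_p: float


def screen_candidates(
    correlations: pd.DataFrame, associations: pd.DataFrame, alpha: float = 0.05
) -> list[MediationCandidate]:
    """Triples meeting both mediation prerequisites.

    A (snp, mediator, outcome) triple qualifies iff the mediator-outcome
    correlation p <= alpha and the SNP is associated with both the mediator
    and the outcome at p <= alpha.  ``correlations`` needs columns
    (mediator, outcome, p); ``associations`` needs (snp, phenotype, p).
    """
    assoc = associations.dropna(subset=["p"])
    by_phen = {
        phen: dict(zip(grp["snp"], grp["p"]))
        for phen, grp in assoc.groupby("phenotype")
    }
    out = []
    for _, row in correlations.iterrows():
        if not row["p"] <= alpha:
            continue
        med, outc = row["mediator"], row["outcome"]
        med_p = by_phen.get(med, {})
        out_p = by_phen.get(outc, {})
        for snp, p_med in med_p.items():
            p_out = out_p.get(snp)
            if p_out is None:
                continue
            if p_med <= alpha and p_out <= alpha:
                out.append(
                    MediationCandidate(
                        snp=snp,
                        mediator=med,
                        outcome=outc,
                        mediator_outcome_p=float(row["p"]),
                        snp_mediator_p=float(p_med),
                        snp_outcome_p=float(p_out),
                    )
                )
    return sorted(out, key=lambda c: (c.snp, c.mediator, c.outcome))


def dominant_code(dosages: np.ndarray) -> np.ndarray:
    """Carrier indicator: 0 for zero minor alleles, 1 otherwise; nan kept."""
    x = np.asarray(dosages, dtype=float)
    return np.where(np.isnan(x), np.nan, (x > 0).astype(float))


# ----------------------------------------------------------------------
# genome principal components
# ----------------------------------------------------------------------
@dataclass
class GenomePCs:
    components: pd.DataFrame  # samples x k, indexed by iid
    eigenvalues: np.ndarray


def genome_pcs(g: GenotypeMatrix, k: int = 10) -> GenomePCs:
    """Top-k PCs of the standardized genotype matrix (sample side).

    Eigenvectors of Z Z' / M with per-PC sign fixed so the largest-magnitude
    loading is positive.  If k exceeds the matrix rank, fewer PCs are
    returned with a warning.
    """
    import warnings

    d = g.dosage.copy()
    mu = np.nanmean(d, axis=0)
    d = np.where(np.isnan(d), mu[None, :], d)
    sd = d.std(axis=0)
    poly = sd > 0
    z = (d[:, poly] - d[:, poly].mean(axis=0)) / sd[poly]
    u, svals, _ = np.linalg.svd(z, full_matrices=False)
    tol = svals.max() * max(z.shape) * np.finfo(float).eps
    rank = int((svals > tol).sum())
    if k > rank:
        warnings.warn(f"requested {k} PCs but rank is {rank}; returning {rank}")
        k = rank
    pcs = u[:, :k]
    for j in range(k):
        if pcs[np.argmax(np.abs(pcs[:, j])), j] < 0:
            pcs[:, j] = -pcs[:, j]
    eig = (svals[:k] ** 2) / z.shape[1]
    comp = pd.DataFrame(
        pcs,
        index=pd.Index(g.sample_ids, name="iid"),
        columns=[f"PC{j + 1}" for j in range(k)],
    )
    return GenomePCs(components=comp, eigenvalues=eig)


def select_pc_covariates(
    pcs: GenomePCs, outcomes: pd.DataFrame, alpha: float = 0.05
) -> dict[str, list[str]]:
    """Attach PC j to outcome k iff their Pearson correlation has p <= alpha."""
    shared = pcs.components.index.intersection(outcomes.index)
    comp = pcs.components.loc[shared]
    out: dict[str, list[str]] = {}
    for col in outcomes.columns:
        y = outcomes.loc[shared, col]
        ok = y.notna()
        chosen = []
        for pc in comp.columns:
            _, p = stats.pearsonr(comp.loc[ok, pc], y[ok])
            if p <= alpha:
                chosen.append(pc)
        out[col] = chosen
    return out


# ----------------------------------------------------------------------
# the path model
# ----------------------------------------------------------------------
@dataclass
class PathModelSpec:
    """Recursive mediation path model specification."""

    exposure: str
    mediator: str
    outcomes: list[str]
    covariates: list[str] = field(default_factory=lambda: ["sex", "age"])
    pc_assignments: dict[str, list[str]] = field(default_factory=dict)
    free_outcome_residual_cov: bool = True

    def __post_init__(self) -> None:
        if self.mediator in self.outcomes:
            raise ValueError("mediator cannot also be an outcome")
        if self.exposure in self.outcomes or self.exposure == self.mediator:
            raise ValueError("exposure must be exogenous")

    @property
    def exogenous(self) -> list[str]:
        pcs = sorted({pc for lst in self.pc_assignments.values() for pc in lst})
        return [self.exposure] + list(self.covariates) + pcs

    @property
    def endogenous(self) -> list[str]:
        return [self.mediator] + list(self.outcomes)

    def regressors(self, endo: str) -> list[str]:
        if endo == self.mediator:
            return [self.exposure] + list(self.covariates)
        return (
            [self.mediator, self.exposure]
            + list(self.covariates)
            + list(self.pc_assignments.get(endo, []))
        )


@dataclass
class PathModelFit:
    spec: PathModelSpec
    n: int
    coefficients: pd.DataFrame  # columns: equation, term, estimate
    robust_cov: np.ndarray
    param_index: list  # (equation, term) per robust_cov row
    sigma_model: np.ndarray
    sigma_sample: np.ndarray
    variables: list[str]
    T: float
    df: int
    p: float
    rmsea: float
    cfi: float
    tli: float

    def coef(self, equation: str, term: str) -> float:
        sel = self.coefficients[
            (self.coefficients["equation"] == equation)
            & (self.coefficients["term"] == term)
        ]
        if sel.empty:
            raise KeyError(f"no path {term!r} in equation {equation!r}")
        return float(sel["estimate"].iloc[0])

    def param_pos(self, equation: str, term: str) -> int:
        try:
            return self.param_index.index((equation, term))
        except ValueError as exc:
            raise KeyError(f"no path {term!r} in equation {equation!r}") from exc

    def model_sd(self, variable: str) -> float:
        i = self.variables.index(variable)
        return float(np.sqrt(self.sigma_model[i, i]))


def fit_indices(T: float, df: int, n: int, T_base: float | None = None, df_base: int | None = None):
    """RMSEA (and CFI/TLI when a baseline is supplied) from T, df, n."""
    if df > 0:
        rmsea = float(np.sqrt(max(T - df, 0.0) / (df * (n - 1))))
        p = float(stats.chi2.sf(T, df))
    else:
        rmsea, p = 0.0, 1.0
    cfi = tli = np.nan
    if T_base is not None and df_base:
        num = max(T - df, 0.0)
        den = max(T_base - df_base, T - df, 0.0)
        cfi = 1.0 if den == 0 else float(1.0 - num / den)
        base_ratio = T_base / df_base
        if df > 0 and base_ratio > 1:
            tli = float((base_ratio - T / df) / (base_ratio - 1.0))
        else:
            tli = 1.0
    return rmsea, p, cfi, tli


def _implied_sigma(spec, coefs, psi, phi, variables):
    """Model-implied covariance from path matrices (reduced form)."""
    exog, endo = spec.exogenous, spec.endogenous
    qx, qe = len(exog), len(endo)
    B = np.zeros((qe, qe))
    G = np.zeros((qe, qx))
    for i, eq in enumerate(endo):
        for term in spec.regressors(eq):
            c = coefs[(eq, term)]
            if term in endo:
                B[i, endo.index(term)] = c
            else:
                G[i, exog.index(term)] = c
    A = np.linalg.inv(np.eye(qe) - B)
    syy = A @ (G @ phi @ G.T + psi) @ A.T
    syx = A @ G @ phi
    sigma = np.zeros((qx + qe, qx + qe))
    sigma[:qx, :qx] = phi
    sigma[qx:, :qx] = syx
    sigma[:qx, qx:] = syx.T
    sigma[qx:, qx:] = syy
    return sigma


def _discrepancy(S, sigma):
    p = S.shape[0]
    sign, logdet_sigma = np.linalg.slogdet(sigma)
    if sign <= 0:
        return np.inf
    _, logdet_s = np.linalg.slogdet(S)
    return float(
        logdet_sigma + np.trace(S @ np.linalg.inv(sigma)) - logdet_s - p
    )


def fit_path_model(
    data: pd.DataFrame, spec: PathModelSpec, estimator: str = "ml_robust"
) -> PathModelFit:
    """Fit the recursive path model on complete cases.

    Estimation: equation-wise OLS, then (when df > 0) a numerical ML polish
    minimizing the multivariate-normal discrepancy F over the path
    coefficients and free residual (co)variances with the exogenous block
    held saturated.  T = (n - 1) * F_min.
    """
    if estimator not in ("ml", "ml_robust"):
        raise ValueError("estimator must be 'ml' or 'ml_robust'")
    variables = spec.exogenous + spec.endogenous
    missing = [v for v in variables if v not in data.columns]
    if missing:
        raise ValueError(f"data lacks model variables: {missing}")
    frame = data[variables].dropna()
    n = len(frame)
    if n <= len(variables) + 2:
        raise ValueError("too few complete cases for the model")
    S = np.cov(frame.to_numpy(dtype=float), rowvar=False, ddof=1)
    if np.linalg.matrix_rank(S) < S.shape[0]:
        raise ValueError("singular sample covariance")

    endo, exog = spec.endogenous, spec.exogenous
    # ---------------- equation-wise OLS ----------------
    coefs: dict = {}
    designs: dict = {}
    resids: dict = {}
    for eq in endo:
        regs = spec.regressors(eq)
        X = np.column_stack(
            [np.ones(n)] + [frame[r].to_numpy(dtype=float) for r in regs]
        )
        y = frame[eq].to_numpy(dtype=float)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        designs[eq] = (X, regs)
        resids[eq] = y - X @ beta
        for name, b in zip(["const"] + regs, beta):
            coefs[(eq, name)] = float(b)

    qe = len(endo)
    psi = np.zeros((qe, qe))
    free_psi_pairs = []
    for i in range(qe):
        psi[i, i] = resids[endo[i]] @ resids[endo[i]] / (n - 1)
    if spec.free_outcome_residual_cov:
        for i in range(1, qe):
            for j in range(i + 1, qe):  # outcome block only (mediator is row 0)
                cov_ij = resids[endo[i]] @ resids[endo[j]] / (n - 1)
                psi[i, j] = psi[j, i] = cov_ij
                free_psi_pairs.append((i, j))
    phi = np.cov(frame[exog].to_numpy(dtype=float), rowvar=False, ddof=1)
    phi = np.atleast_2d(phi)

    # ---------------- degrees of freedom ----------------
    p_obs = len(variables)
    n_paths = sum(len(spec.regressors(eq)) for eq in endo)
    n_free = (
        len(exog) * (len(exog) + 1) // 2  # saturated exogenous block
        + n_paths
        + qe  # residual variances
        + len(free_psi_pairs)
    )
    df = p_obs * (p_obs + 1) // 2 - n_free
    if df < 0:
        raise ValueError("model has more free parameters than moments")

    # ---------------- ML polish when over-identified ----------------
    path_keys = [(eq, r) for eq in endo for r in spec.regressors(eq)]
    if df > 0:
        def pack():
            vals = [coefs[k] for k in path_keys]
            vals += [psi[i, i] for i in range(qe)]
            vals += [psi[i, j] for i, j in free_psi_pairs]
            return np.array(vals)

        def objective(theta):
            c = dict(coefs)
            k = len(path_keys)
            for key, val in zip(path_keys, theta[:k]):
                c[key] = val
            ps = np.zeros((qe, qe))
            for i in range(qe):
                v = theta[k + i]
                if v <= 0:
                    return np.inf
                ps[i, i] = v
            for idx, (i, j) in enumerate(free_psi_pairs):
                ps[i, j] = ps[j, i] = theta[k + qe + idx]
            sigma = _implied_sigma(spec, c, ps, phi, variables)
            return _discrepancy(S, sigma)

        res = optimize.minimize(objective, pack(), method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 20000})
        theta = res.x
        k = len(path_keys)
        for key, val in zip(path_keys, theta[:k]):
            coefs[key] = float(val)
        for i in range(qe):
            psi[i, i] = theta[k + i]
        for idx, (i, j) in enumerate(free_psi_pairs):
            psi[i, j] = psi[j, i] = theta[k + qe + idx]

    sigma = _implied_sigma(spec, coefs, psi, phi, variables)
    F = max(_discrepancy(S, sigma), 0.0)
    T = (n - 1) * F

    # baseline (independence) model for CFI/TLI
    F_base = float(np.log(np.diag(S)).sum() - np.linalg.slogdet(S)[1])
    T_base = (n - 1) * F_base
    df_base = p_obs * (p_obs - 1) // 2
    rmsea, p_val, cfi, tli = fit_indices(T, df, n, T_base, df_base)

    # ---------------- joint coefficient covariance ----------------
    param_index = []
    blocks = []
    grads = []
    for eq in endo:
        X, regs = designs[eq]
        param_index += [(eq, t) for t in ["const"] + regs]
        blocks.append(X.T @ X)
        grads.append(X * resids[eq][:, None])
    A = np.zeros((len(param_index), len(param_index)))
    ofs = 0
    slices = []
    for blk in blocks:
        k = blk.shape[0]
        A[ofs : ofs + k, ofs : ofs + k] = blk
        slices.append(slice(ofs, ofs + k))
        ofs += k
    G = np.hstack(grads)
    A_inv = np.linalg.inv(A)
    if estimator == "ml_robust":
        robust_cov = A_inv @ (G.T @ G) @ A_inv  # HC0 sandwich
    else:
        omega = np.zeros_like(A)
        for i, eq_i in enumerate(endo):
            Xi, _ = designs[eq_i]
            for j, eq_j in enumerate(endo):
                Xj, _ = designs[eq_j]
                omega[slices[i], slices[j]] = psi[i, j] * (Xi.T @ Xj) / 1.0
        robust_cov = A_inv @ omega @ A_inv

    coeff_rows = [
        {"equation": eq, "term": term, "estimate": coefs[(eq, term)]}
        for (eq, term) in param_index
    ]
    return PathModelFit(
        spec=spec,
        n=n,
        coefficients=pd.DataFrame(coeff_rows),
        robust_cov=robust_cov,
        param_index=param_index,
        sigma_model=sigma,
        sigma_sample=S,
        variables=variables,
        T=float(T),
        df=int(df),
        p=p_val,
        rmsea=rmsea,
        cfi=cfi,
        tli=tli,
    )


# ----------------------------------------------------------------------
# indirect effects and verdicts
# ----------------------------------------------------------------------
def indirect_effects(
    fit: PathModelFit,
    outcomes: list[str] | None = None,
    standardized: bool = True,
) -> pd.DataFrame:
    """Indirect effects a * b_k with delta-method SEs.

    Var(ab) = b^2 Var(a) + a^2 Var(b) + 2ab Cov(a, b); standardization
    divides estimate and SE by the model-implied outcome SD.
    """
    spec = fit.spec
    outcomes = outcomes or spec.outcomes
    ia = fit.param_pos(spec.mediator, spec.exposure)
    a = fit.coef(spec.mediator, spec.exposure)
    va = fit.robust_cov[ia, ia]
    rows = []
    for out in outcomes:
        ib = fit.param_pos(out, spec.mediator)
        b = fit.coef(out, spec.mediator)
        vb = fit.robust_cov[ib, ib]
        cab = fit.robust_cov[ia, ib]
        est = a * b
        var = b * b * va + a * a * vb + 2 * a * b * cab
        se = float(np.sqrt(max(var, 0.0)))
        scale = fit.model_sd(out) if standardized else 1.0
        z = est / se if se > 0 else np.nan
        rows.append(
            {
                "outcome": out,
                "indirect": est / scale,
                "se": se / scale,
                "p": float(2 * stats.norm.sf(abs(z))) if se > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def direct_effects(fit: PathModelFit, standardized: bool = True) -> pd.DataFrame:
    """Direct exposure -> outcome paths with robust SEs."""
    spec = fit.spec
    rows = []
    for out in [spec.mediator] + spec.outcomes:
        i = fit.param_pos(out, spec.exposure)
        est = fit.coef(out, spec.exposure)
        se = float(np.sqrt(fit.robust_cov[i, i]))
        scale = fit.model_sd(out) if standardized else 1.0
        z = est / se if se > 0 else np.nan
        rows.append(
            {
                "outcome": out,
                "direct": est / scale,
                "se": se / scale,
                "p": float(2 * stats.norm.sf(abs(z))) if se > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def mediation_verdict(
    fit: PathModelFit,
    adjusted_scan: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Classify each outcome: total mediation / partial / none.

    total: indirect p <= alpha and direct p > alpha; partial: both <= alpha;
    none: indirect p > alpha.  When mediator-adjusted scan records are
    supplied, a column notes whether the SNP remained significant there.
    """
    ind = indirect_effects(fit).set_index("outcome")
    dire = direct_effects(fit).set_index("outcome")
    rows = []
    for out in fit.spec.outcomes:
        ip, dp = ind.loc[out, "p"], dire.loc[out, "p"]
        if ip <= alpha and dp > alpha:
            verdict = "total mediation"
        elif ip <= alpha:
            verdict = "partial"
        else:
            verdict = "none"
        row = {
            "outcome": out,
            "indirect": ind.loc[out, "indirect"],
            "indirect_p": ip,
            "direct": dire.loc[out, "direct"],
            "direct_p": dp,
            "verdict": verdict,
        }
        if adjusted_scan is not None:
            sel = adjusted_scan[adjusted_scan["phenotype"] == out]
            row["adjusted_scan_significant"] = (
                bool((sel["p"] <= alpha).any()) if not sel.empty else None
            )
        rows.append(row)
    return pd.DataFrame(rows)
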