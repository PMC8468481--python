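"""Genotype input and the quality-control cascade.

The cascade: biallelic/MAF filter -> iterative missingness (variants first,
then samples, at thresholds 0.1, 0.05, 0.01) -> Hardy-Weinberg exact test
(the SNP set is final after this step) -> LD pruning to an independent SNP
set used only for the sample-level filters -> optional identity-by-descent
relatedness filter -> heterozygosity outlier filter.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .containers import GenotypeMatrix
from .plink import read_plink

logger = logging.getLogger(__name__)


@dataclass
class QCConfig:
    """Thresholds of the QC cascade (defaults follow standard array QC)."""

    maf_min: float = 0.01
    missing_max: float = 0.01
    missing_schedule: tuple[float, ...] = (0.1, 0.05, 0.01)
    hwe_p_min: float = 1e-5
    prune_window: int = 1500
    prune_step: int = 150
    prune_r2_max: float = 0.2
    het_sd_bound: float = 3.0
    ibd_threshold: float = 0.1875

    def __post_init__(self) -> None:
        if not 0 <= self.maf_min <= 0.5:
            raise ValueError("maf_min must be in [0, 0.5]")
        if list(self.missing_schedule) != sorted(self.missing_schedule, reverse=True) or len(
            set(self.missing_schedule)
        ) != len(self.missing_schedule):
            raise ValueError("missing_schedule must be strictly decreasing")
        if not 0 < self.hwe_p_min < 1:
            raise ValueError("hwe_p_min must be in (0, 1)")
        if self.prune_step < 1 or self.prune_window < 2:
            raise ValueError("invalid pruning window/step")


@dataclass
class QCReport:
    """Per-step removal bookkeeping for a QC run."""

    steps: list = field(default_factory=list)  # (step, kind, removed ids)
    snp_stats: pd.DataFrame | None = None
    sample_stats: pd.DataFrame | None = None

    def record(self, step: str, kind: str, removed_ids) -> None:
        self.steps.append(
            {"step": step, "kind": kind, "n_removed": len(removed_ids), "removed": list(removed_ids)}
        )

    def removed(self, step: str | None = None, kind: str | None = None) -> list:
        out = []
        for s in self.steps:
            if (step is None or s["step"] == step) and (kind is None or s["kind"] == kind):
                out.extend(s["removed"])
        return out

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{k: s[k] for k in ("step", "kind", "n_removed")} for s in self.steps]
        )

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.steps, fh, indent=2, default=str)


class EmptyResultError(RuntimeError):
    """Raised when a filter removes every SNP or sample."""


# ----------------------------------------------------------------------
# input
# ----------------------------------------------------------------------
def read_genotypes(path: str, format: str = "plink") -> GenotypeMatrix:
    """Read genotypes from a PLINK prefix or a VCF file.

    Only biallelic single-nucleotide variants are retained (multi-allelic
    or indel records are skipped with a warning).  Dosages are relabeled to
    count the minor allele.
    """
    if format == "plink":
        g = read_plink(path)
    elif format == "vcf":
        g = _read_vcf(path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")
    return _relabel_minor(g)


def _read_vcf(path: str) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(path)
    sample_ids = list(vcf.samples)
    rows = []
    cols = []
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            logger.warning("skipping non-biallelic-SNV record %s:%s", v.CHROM, v.POS)
            continue
        # gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
        gt = v.gt_types
        dos = np.choose(gt, [0.0, 1.0, np.nan, 2.0])
        cols.append(dos)
        chrom = str(v.CHROM).removeprefix("chr")
        rows.append(
            {
                "snp": v.ID or f"{v.CHROM}:{v.POS}",
                "chrom": int(chrom),
                "pos": v.POS,
                "a1": v.ALT[0],
                "a2": v.REF,
            }
        )
    dosage = (
        np.column_stack(cols) if cols else np.empty((len(sample_ids), 0))
    )
    snps = pd.DataFrame(rows, columns=["snp", "chrom", "pos", "a1", "a2"])
    samples = pd.DataFrame({"fid": sample_ids, "iid": sample_ids, "sex": 0})
    return GenotypeMatrix(dosage=dosage, snps=snps, samples=samples)


def _relabel_minor(g: GenotypeMatrix) -> GenotypeMatrix:
    """Flip SNPs so the counted (a1) allele is the minor one."""
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(g.dosage, axis=0) / 2.0
    flip = freq > 0.5
    if flip.any():
        g = g.copy()
        g.dosage[:, flip] = 2.0 - g.dosage[:, flip]
        a1 = g.snps.loc[flip, "a1"].copy()
        g.snps.loc[flip, "a1"] = g.snps.loc[flip, "a2"].to_numpy()
        g.snps.loc[flip, "a2"] = a1.to_numpy()
    return g


# ----------------------------------------------------------------------
# per-SNP statistics
# ----------------------------------------------------------------------
def maf(g: GenotypeMatrix | np.ndarray) -> np.ndarray:
    """Per-SNP minor allele frequency (nan for all-missing SNPs).

    MAF = (2 * minor-hom + het) / (2 * non-missing), folded to <= 0.5.
    """
    dosage = g.dosage if isinstance(g, GenotypeMatrix) else np.atleast_2d(np.asarray(g, float).T).T
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(dosage, axis=0) / 2.0
    return np.minimum(freq, 1.0 - freq)


def genotype_counts(dosages: np.ndarray) -> tuple[int, int, int]:
    """(hom-minor, het, hom-major) counts of one SNP's dosage vector."""
    d = dosages[~np.isnan(dosages)]
    return int((d == 2).sum()), int((d == 1).sum()), int((d == 0).sum())


def hwe_exact_test(hom1: int, het: int, hom2: int) -> float:
    """Two-sided exact Hardy-Weinberg test (conditional on allele counts).

    Sums the probabilities of all heterozygote counts whose conditional
    probability does not exceed that of the observed count (plain exact
    test, no mid-p).
    """
    if min(hom1, het, hom2) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = hom1 + het + hom2
    if n < 1:
        raise ValueError("at least one genotype required")
    n_minor = 2 * hom1 + het
    n_minor = min(n_minor, 2 * n - n_minor)
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    hom_a = (n_minor - hets) // 2
    hom_b = n - hets - hom_a
    valid = hom_b >= 0
    hets, hom_a, hom_b = hets[valid], hom_a[valid], hom_b[valid]
    logp = (
        gammaln(n + 1)
        - gammaln(hom_a + 1)
        - gammaln(hets + 1)
        - gammaln(hom_b + 1)
        + hets * np.log(2.0)
        + gammaln(n_minor + 1)
        + gammaln(2 * n - n_minor + 1)
        - gammaln(2 * n + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    obs = probs[hets == het]
    if obs.size == 0:  # inconsistent observed configuration
        raise ValueError("observed het count incompatible with allele counts")
    return float(probs[probs <= obs[0] * (1 + 1e-12)].sum())


def hwe_pvalues(g: GenotypeMatrix) -> np.ndarray:
    return np.array(
        [hwe_exact_test(*genotype_counts(g.dosage[:, j])) for j in range(g.n_snps)]
    )


# ----------------------------------------------------------------------
# filters
# ----------------------------------------------------------------------
def maf_filter(g: GenotypeMatrix, maf_min: float) -> tuple[GenotypeMatrix, list]:
    m = maf(g)
    keep = np.flatnonzero(~(np.isnan(m) | (m < maf_min)))
    removed = [s for s in g.snp_ids if s not in set(g.snp_ids[keep])]
    return g.subset(snp_idx=keep), removed


def iterative_missingness_filter(
    g: GenotypeMatrix, schedule=(0.1, 0.05, 0.01)
) -> tuple[GenotypeMatrix, list, list]:
    """Variants-then-samples missingness filtering at a decreasing schedule.

    Returns (filtered matrix, removed SNP ids, removed sample ids).
    """
    if len(schedule) == 0:
        raise ValueError("schedule must be nonempty")
    removed_snps: list = []
    removed_samples: list = []
    for thr in schedule:
        snp_miss = g.missing_rate_per_snp()
        keep = np.flatnonzero(snp_miss <= thr)
        removed_snps.extend(np.setdiff1d(g.snp_ids, g.snp_ids[keep]).tolist())
        g = g.subset(snp_idx=keep)
        if g.n_snps == 0:
            raise EmptyResultError("missingness filter removed every SNP")
        sample_miss = g.missing_rate_per_sample()
        keep = np.flatnonzero(sample_miss <= thr)
        removed_samples.extend(np.setdiff1d(g.sample_ids, g.sample_ids[keep]).tolist())
        g = g.subset(sample_idx=keep)
        if g.n_samples == 0:
            raise EmptyResultError("missingness filter removed every sample")
    return g, removed_snps, removed_samples


def ld_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors (pairwise complete)."""
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 2:
        raise ValueError("need >= 2 jointly non-missing samples")
    xs, ys = x[ok], y[ok]
    if xs.std() == 0 or ys.std() == 0:
        return np.nan
    r = np.corrcoef(xs, ys)[0, 1]
    return float(r * r)


def _window_r2(dosage: np.ndarray) -> np.ndarray:
    """Pairwise r^2 of the columns of a dosage block, pairwise-complete."""
    df = pd.DataFrame(dosage)
    r = df.corr().to_numpy()
    return r * r


def ld_prune(
    g: GenotypeMatrix, window: int = 1500, step: int = 150, r2_max: float = 0.2
) -> np.ndarray:
    """Greedy sliding-window LD pruning; returns retained SNP indices.

    Within each window the first (lexicographically smallest) violating pair
    is resolved by removing the member with higher missingness, ties broken
    by later position; windows slide by ``step`` per chromosome and sweeps
    repeat until a full pass removes nothing.
    """
    removed: set[int] = set()
    miss = g.missing_rate_per_snp()
    for chrom in pd.unique(g.snps["chrom"]):
        idx_all = np.flatnonzero((g.snps["chrom"] == chrom).to_numpy())
        changed = True
        while changed:
            changed = False
            for start in range(0, len(idx_all), step):
                win = [i for i in idx_all[start : start + window] if i not in removed]
                while len(win) >= 2:
                    r2 = _window_r2(g.dosage[:, win])
                    pair = None
                    for a in range(len(win)):
                        for b in range(a + 1, len(win)):
                            if r2[a, b] > r2_max:
                                pair = (a, b)
                                break
                        if pair:
                            break
                    if pair is None:
                        break
                    a, b = pair
                    ia, ib = win[a], win[b]
                    if miss[ia] > miss[ib]:
                        victim = ia
                    else:  # equal missingness -> later position
                        victim = ib
                    removed.add(victim)
                    win.remove(victim)
                    changed = True
                if start + window >= len(idx_all):
                    break
    return np.array([i for i in range(g.n_snps) if i not in removed], dtype=int)


def heterozygosity_f(g: GenotypeMatrix, snp_idx=None) -> np.ndarray:
    """Per-sample inbreeding-style F from observed vs expected homozygosity.

    F = (O_hom - E_hom) / (N - E_hom) with expectations from the current
    sample allele frequencies, summed over the sample's non-missing SNPs.
    """
    d = g.dosage if snp_idx is None else g.dosage[:, snp_idx]
    with np.errstate(invalid="ignore"):
        p = np.nanmean(d, axis=0) / 2.0
    exp_het = 2.0 * p * (1.0 - p)
    nonmiss = ~np.isnan(d)
    obs_hom = ((d == 0) | (d == 2)).sum(axis=1)
    n_typed = nonmiss.sum(axis=1)
    e_hom = (nonmiss * (1.0 - exp_het)[None, :]).sum(axis=1)
    denom = n_typed - e_hom
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, (obs_hom - e_hom) / denom, 0.0)


def heterozygosity_filter(
    g: GenotypeMatrix, sd_bound: float = 3.0, snp_idx=None
) -> tuple[np.ndarray, np.ndarray]:
    """Retained sample indices + per-sample F, dropping |F - mean| > k*SD."""
    f = heterozygosity_f(g, snp_idx)
    sd = f.std()
    if sd == 0:
        logger.info("heterozygosity SD is zero; no samples removed")
        return np.arange(g.n_samples), f
    keep = np.flatnonzero(np.abs(f - f.mean()) <= sd_bound * sd)
    return keep, f


def ibd_pihat(g: GenotypeMatrix, snp_idx=None) -> np.ndarray:
    """Pairwise PI_HAT by method-of-moments from IBS counts.

    Solves the IBS-given-IBD mixture for P(IBD=0,1,2) per pair using the
    asymptotic expected IBS probabilities at the sample allele frequencies
    (no finite-sample allele-count correction), clamps to [0, 1], and
    returns PI_HAT = P1/2 + P2.
    """
    d = g.dosage if snp_idx is None else g.dosage[:, snp_idx]
    n, m = d.shape
    with np.errstate(invalid="ignore"):
        p = np.nanmean(d, axis=0) / 2.0
    q = 1.0 - p
    # expected per-locus IBS probabilities given IBD state
    e0_ibs0 = 2 * p**2 * q**2
    e0_ibs1 = 4 * p**3 * q + 4 * p * q**3
    e0_ibs2 = p**4 + 4 * p**2 * q**2 + q**4
    e1_ibs1 = 2 * p * q  # given IBD=1
    e1_ibs2 = p**2 + q**2

    nonmiss = ~np.isnan(d)
    B = nonmiss.astype(float)
    n_valid = B @ B.T
    ind = {v: (np.nan_to_num(d) == v) * nonmiss for v in (0.0, 1.0, 2.0)}
    ibs2 = sum((ind[v].astype(float) @ ind[v].astype(float).T) for v in (0.0, 1.0, 2.0))
    a0, a2 = ind[0.0].astype(float), ind[2.0].astype(float)
    ibs0 = a0 @ a2.T + a2 @ a0.T
    ibs1 = n_valid - ibs2 - ibs0

    # per-pair expected sums approximated by the all-locus sums scaled by
    # the pair's non-missing fraction (exact when there is no missingness)
    frac = n_valid / m
    s0_ibs0 = e0_ibs0.sum() * frac
    s0_ibs1 = e0_ibs1.sum() * frac
    s0_ibs2 = e0_ibs2.sum() * frac
    s1_ibs1 = e1_ibs1.sum() * frac
    s1_ibs2 = e1_ibs2.sum() * frac

    # the IBD-state proportions are left unclamped so their sampling noise
    # stays symmetric; only the final PI_HAT is clamped to [0, 1]
    with np.errstate(invalid="ignore", divide="ignore"):
        p0 = ibs0 / s0_ibs0
        p1 = (ibs1 - p0 * s0_ibs1) / s1_ibs1
        p2 = (ibs2 - p0 * s0_ibs2 - p1 * s1_ibs2) / n_valid
    pihat = p1 / 2.0 + p2
    np.fill_diagonal(pihat, 1.0)
    return np.clip(pihat, 0.0, 1.0)


def ibd_filter(
    g: GenotypeMatrix, threshold: float = 0.1875, snp_idx=None
) -> tuple[np.ndarray, np.ndarray]:
    """Break related pairs above the PI_HAT threshold, keeping one member.

    The member with higher missingness is removed; ties keep the earlier
    sample id.  Returns (retained sample indices, full PI_HAT matrix).
    """
    pihat = ibd_pihat(g, snp_idx)
    miss = g.missing_rate_per_sample()
    ids = g.sample_ids
    active = set(range(g.n_samples))
    work = pihat.copy()
    np.fill_diagonal(work, 0.0)
    while True:
        sub = sorted(active)
        block = work[np.ix_(sub, sub)]
        mx = block.max(initial=0.0)
        if mx <= threshold:
            break
        a, b = np.argwhere(block == mx)[0]
        i, j = sub[a], sub[b]
        if miss[i] > miss[j]:
            victim = i
        elif miss[j] > miss[i]:
            victim = j
        else:
            victim = j if ids[i] <= ids[j] else i
        active.discard(victim)
    return np.array(sorted(active), dtype=int), pihat


# ----------------------------------------------------------------------
# the cascade
# ----------------------------------------------------------------------
def run_qc(
    g: GenotypeMatrix, config: QCConfig | None = None, mode: str = "all"
) -> tuple[GenotypeMatrix, QCReport]:
    """Run the full QC cascade; ``mode='unrelated'`` adds the IBD filter."""
    if mode not in ("all", "unrelated"):
        raise ValueError("mode must be 'all' or 'unrelated'")
    config = config or QCConfig()
    report = QCReport()

    g1, removed = maf_filter(g, config.maf_min)
    report.record("maf", "snp", removed)

    g2, rs, rsam = iterative_missingness_filter(g1, config.missing_schedule)
    report.record("missingness", "snp", rs)
    report.record("missingness", "sample", rsam)

    hwe_p = hwe_pvalues(g2)
    keep = np.flatnonzero(hwe_p >= config.hwe_p_min)
    report.record("hwe", "snp", np.setdiff1d(g2.snp_ids, g2.snp_ids[keep]).tolist())
    g3 = g2.subset(snp_idx=keep)
    if g3.n_snps == 0:
        raise EmptyResultError("HWE filter removed every SNP")

    pruned = ld_prune(g3, config.prune_window, config.prune_step, config.prune_r2_max)

    if mode == "unrelated":
        keep_s, pihat = ibd_filter(g3, config.ibd_threshold, pruned)
        report.record("ibd", "sample", np.setdiff1d(g3.sample_ids, g3.sample_ids[keep_s]).tolist())
        g3 = g3.subset(sample_idx=keep_s)

    keep_s, f = heterozygosity_filter(g3, config.het_sd_bound, pruned)
    report.record(
        "heterozygosity", "sample", np.setdiff1d(g3.sample_ids, g3.sample_ids[keep_s]).tolist()
    )
    g4 = g3.subset(sample_idx=keep_s)

    report.snp_stats = pd.DataFrame(
        {
            "snp": g4.snp_ids,
            "maf": maf(g4),
            "missing_rate": g4.missing_rate_per_snp(),
        }
    )
    report.sample_stats = pd.DataFrame(
        {
            "iid": g4.sample_ids,
            "missing_rate": g4.missing_rate_per_sample(),
            "het_f": f[keep_s],
        }
    )
    return g4, report
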