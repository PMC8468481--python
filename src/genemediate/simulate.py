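"""Synthetic genotypes and phenotypes with a known mediation structure.

The generator emulates a single-gene association study: a dense block-LD
region of biallelic SNPs on one chromosome, background SNPs on the other
chromosomes for kinship estimation, related sample pairs, and 18 continuous
phenotypes (one BMI-like anthropometric, four cardiovascular risk scores,
ten psychiatric symptom scale scores, three rumination scale scores).  One
low-frequency focal SNP acts on the symptom scores entirely through the
rumination mediator (carrier-coded), while the cardiovascular scores are
generated independent of both the mediator and the focal SNP.

Path conventions
----------------
``a_path`` is the effect of carrier status (0/1) on the mediator in
mediator-SD units; ``b_paths`` are mediator -> outcome effects per mediator
SD in outcome-SD units; ``direct_paths`` are carrier -> outcome effects in
outcome-SD units (default 0 everywhere: full mediation).  Under this
convention the outcome-SD-standardized indirect effect of the carrier is
exactly ``a * b_k``.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .containers import GenotypeMatrix

CARDIO_PHENOTYPES = [
    "bmi",
    "framingham_cvd",
    "framingham_chd",
    "framingham_hchd",
    "framingham_stroke",
]
SYMPTOM_PHENOTYPES = [
    "bsi_gsi",
    "bsi_somatization",
    "bsi_obsessive_compulsive",
    "bsi_interpersonal_sensitivity",
    "bsi_depression",
    "bsi_anxiety",
    "bsi_hostility",
    "bsi_phobic_anxiety",
    "bsi_paranoid_ideation",
    "bsi_psychoticism",
]
MEDIATOR = "rrs_rumination"
RUMINATION_PHENOTYPES = [MEDIATOR, "rrs_brooding", "rrs_reflection"]
ALL_PHENOTYPES = CARDIO_PHENOTYPES + SYMPTOM_PHENOTYPES + RUMINATION_PHENOTYPES

#: target (mean, SD) on the natural scale of each phenotype
PHENOTYPE_SCALE = {
    "bmi": (27.39, 5.034),
    "framingham_cvd": (13.78, 11.998),
    "framingham_chd": (8.59, 7.821),
    "framingham_hchd": (4.17, 5.097),
    "framingham_stroke": (2.83, 3.288),
    "bsi_gsi": (0.55, 0.508),
    "bsi_somatization": (0.51, 0.617),
    "bsi_obsessive_compulsive": (0.70, 0.703),
    "bsi_interpersonal_sensitivity": (0.94, 0.695),
    "bsi_depression": (0.48, 0.606),
    "bsi_anxiety": (0.54, 0.668),
    "bsi_hostility": (0.50, 0.566),
    "bsi_phobic_anxiety": (0.32, 0.584),
    "bsi_paranoid_ideation": (0.71, 0.673),
    "bsi_psychoticism": (0.42, 0.564),
    "rrs_rumination": (1.89, 0.503),
    "rrs_brooding": (1.91, 0.570),
    "rrs_reflection": (1.86, 0.602),
}

#: mediator -> symptom effects (outcome-SD per mediator-SD)
DEFAULT_B_PATHS = {
    "bsi_gsi": 0.474,
    "bsi_somatization": 0.318,
    "bsi_obsessive_compulsive": 0.380,
    "bsi_interpersonal_sensitivity": 0.360,
    "bsi_depression": 0.474,
    "bsi_anxiety": 0.432,
    "bsi_hostility": 0.347,
    "bsi_phobic_anxiety": 0.318,
    "bsi_paranoid_ideation": 0.370,
    "bsi_psychoticism": 0.370,
}

#: (sex, age) loadings in outcome-SD units; sex coded 0 male / 1 female,
#: age standardized.  Age loads heavily on the cardiovascular risk scores
#: (it is a component of such equations); rumination and symptoms load
#: mildly on sex and age.
DEFAULT_COVARIATE_EFFECTS = {
    **{p: (0.10, 0.55) for p in CARDIO_PHENOTYPES},
    **{p: (0.10, -0.05) for p in SYMPTOM_PHENOTYPES},
    **{p: (0.15, -0.10) for p in RUMINATION_PHENOTYPES},
}


def _default_ld_blocks(n_gene_snps: int, focal_index: int) -> list[tuple[int, float]]:
    """Partition of the gene SNPs into LD blocks.

    A repeating mix of tight (rho 0.95), moderate (0.8), loose (0.6) blocks
    and singletons, with the focal SNP forced into its own singleton block.
    """
    pattern = [(1, 0.0), (8, 0.95), (4, 0.80), (2, 0.60)]
    blocks: list[tuple[int, float]] = []
    total = 0
    i = 0
    while total < n_gene_snps:
        size, rho = pattern[i % len(pattern)]
        size = min(size, n_gene_snps - total)
        blocks.append((size, rho if size > 1 else 0.0))
        total += size
        i += 1
    return blocks


@dataclass
class SimulationSpec:
    """Study conditions for the synthetic cohort."""

    n_samples: int = 795
    n_gene_snps: int = 274
    n_background_snps: int = 2000
    n_chromosomes: int = 22
    gene_chromosome: int = 2
    maf_range: tuple[float, float] = (0.01, 0.5)
    ld_blocks: list[tuple[int, float]] | None = None
    n_related_pairs: int = 80
    focal_index: int = 0
    focal_maf: float = 0.0489
    a_path: float = 0.308
    b_paths: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_B_PATHS))
    direct_paths: dict[str, float] = field(default_factory=dict)
    covariate_effects: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_gene_snps < 1:
            raise ValueError("n_gene_snps must be >= 1")
        if 2 * self.n_related_pairs > self.n_samples:
            raise ValueError(
                f"{self.n_related_pairs} related pairs need "
                f"{2 * self.n_related_pairs} samples, have {self.n_samples}"
            )
        lo, hi = self.maf_range
        if not (0.01 <= lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0.01 <= lo <= hi <= 0.5")
        if self.ld_blocks is None:
            self.ld_blocks = _default_ld_blocks(self.n_gene_snps, self.focal_index)
        if sum(s for s, _ in self.ld_blocks) != self.n_gene_snps:
            raise ValueError("ld_blocks must partition the gene SNPs")
        if not 0 <= self.focal_index < self.n_gene_snps:
            raise ValueError("focal_index out of range")


def _gene_block_haplotypes(rng, n_hap, size, rho, maf):
    """Binary haplotype alleles via a latent equicorrelated Gaussian block."""
    f = rng.standard_normal(n_hap)
    if rho >= 1.0:
        z = np.repeat(f[:, None], size, axis=1)
    else:
        e = rng.standard_normal((n_hap, size))
        z = np.sqrt(rho) * f[:, None] + np.sqrt(1.0 - rho) * e
    return (z < norm.ppf(maf)).astype(np.uint8)


def gen_genotypes(spec: SimulationSpec) -> GenotypeMatrix:
    """Generate the cohort's genotype matrix.

    Gene-region SNPs sit on ``spec.gene_chromosome`` with block-equicorrelated
    latent haplotypes (marginal HWE holds by construction since the two
    haplotypes of a person are independent); background SNPs are spread over
    the remaining chromosomes.  Each related pair shares one full parental
    haplotype (gene-dropping), giving expected kinship ~0.25 / PI_HAT ~0.5.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    lo, hi = spec.maf_range

    hap_cols = []  # (2, n) arrays per SNP, minor-allele indicators
    mafs = []
    snp_pos = 0
    for size, rho in spec.ld_blocks:
        covers_focal = snp_pos <= spec.focal_index < snp_pos + size
        maf = spec.focal_maf if covers_focal else rng.uniform(lo, hi)
        block = _gene_block_haplotypes(rng, 2 * n, size, rho, maf)
        hap_cols.append(block.reshape(2, n, size))
        mafs.extend([maf] * size)
        snp_pos += size
    gene_h = np.concatenate(hap_cols, axis=2)  # (2, n, n_gene)

    bg_maf = rng.uniform(lo, hi, size=spec.n_background_snps)
    bg_h = (rng.random((2, n, spec.n_background_snps)) < bg_maf).astype(np.uint8)

    h = np.concatenate([gene_h, bg_h], axis=2)  # (2, n, m)

    # gene-dropping: second member of each related pair inherits haplotype 0
    # of the first member
    fids = [f"F{i:05d}" for i in range(n)]
    for k in range(spec.n_related_pairs):
        i, j = n - 2 * k - 2, n - 2 * k - 1
        h[0, j] = h[0, i]
        fids[j] = fids[i]

    dosage = (h[0] + h[1]).astype(float)

    # re-draw SNPs whose empirical MAF fell below the admissible minimum
    # (keeps the no-violation QC contract of the generator)
    for _ in range(20):
        freq = dosage.mean(axis=0) / 2.0
        emp_maf = np.minimum(freq, 1.0 - freq)
        bad = np.flatnonzero(emp_maf < lo)
        bad = bad[bad != spec.focal_index]  # focal MAF is a fixed condition
        if bad.size == 0:
            break
        for idx in bad:
            maf = rng.uniform(max(lo, 0.05), hi)
            col = (rng.random((2, n)) < maf).astype(np.uint8)
            for k in range(spec.n_related_pairs):
                i, j = n - 2 * k - 2, n - 2 * k - 1
                col[0, j] = col[0, i]
            dosage[:, idx] = (col[0] + col[1]).astype(float)

    m_gene = spec.n_gene_snps
    chroms = np.empty(dosage.shape[1], dtype=int)
    pos = np.empty(dosage.shape[1], dtype=int)
    chroms[:m_gene] = spec.gene_chromosome
    pos[:m_gene] = 10_000 + 200 * np.arange(m_gene)
    other = [c for c in range(1, spec.n_chromosomes + 1) if c != spec.gene_chromosome]
    if spec.n_background_snps > 0 and not other:
        raise ValueError("background SNPs need at least one non-gene chromosome")
    for j in range(spec.n_background_snps):
        chroms[m_gene + j] = other[j % len(other)]
        pos[m_gene + j] = 50_000 + 1_000 * (j // len(other))

    snp_ids = [f"g{i:04d}" for i in range(m_gene)] + [
        f"b{i:05d}" for i in range(spec.n_background_snps)
    ]
    snps = pd.DataFrame(
        {
            "snp": snp_ids,
            "chrom": chroms,
            "pos": pos,
            "a1": "A",
            "a2": "G",
            "is_focal": [i == spec.focal_index for i in range(len(snp_ids))],
        }
    )
    samples = pd.DataFrame(
        {
            "fid": fids,
            "iid": [f"S{i:05d}" for i in range(n)],
            "sex": rng.integers(1, 3, size=n),  # 1 male, 2 female
        }
    )
    # order is not position-sorted per chromosome for background interleaving;
    # sort gene first (already sorted), background by (chrom, pos)
    order = np.lexsort((pos, chroms != spec.gene_chromosome, chroms))
    g = GenotypeMatrix(dosage=dosage, snps=snps, samples=samples)
    return g.subset(snp_idx=order)


def focal_snp_index(g: GenotypeMatrix) -> int:
    idx = np.flatnonzero(g.snps["is_focal"].to_numpy())
    if idx.size != 1:
        raise ValueError("genotype matrix does not designate a unique focal SNP")
    return int(idx[0])


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        raise ValueError("degenerate covariate with zero variance")
    return (x - x.mean()) / sd


def gen_phenotypes(g: GenotypeMatrix, spec: SimulationSpec) -> pd.DataFrame:
    """Generate the 18 phenotypes plus sex and age for a genotype matrix.

    mediator = a * carrier + covariates + noise (mediator-SD scale);
    symptom_k = b_k * mediator + direct_k * carrier + covariates + noise;
    cardiovascular scores depend only on sex, age, and noise.  Each column
    is then mapped onto its natural scale via the target mean/SD table.
    """
    rng = np.random.default_rng(spec.seed + 1)
    n = g.n_samples
    focal = focal_snp_index(g)
    dos = g.dosage[:, focal]
    carrier = (np.nan_to_num(dos, nan=0.0) > 0).astype(float)
    if carrier.std() == 0:
        raise ValueError("focal SNP is monomorphic; no carrier contrast")

    sex_f = (g.samples["sex"].to_numpy() == 2).astype(float)
    age = rng.uniform(20.0, 80.0, size=n)
    zsex = sex_f - sex_f.mean()
    zage = _standardize(age)

    def noise(explained: float) -> np.ndarray:
        return np.sqrt(max(1.0 - explained, 0.05)) * rng.standard_normal(n)

    cov = spec.covariate_effects
    a = spec.a_path
    s_m, g_m = cov[MEDIATOR]
    var_c = carrier.var()
    med_star = a * carrier + s_m * zsex + g_m * zage
    med_star = med_star + noise(a * a * var_c + s_m * s_m * 0.25 + g_m * g_m)

    data = {"sex": sex_f, "age": age}
    for name in CARDIO_PHENOTYPES:
        s_k, g_k = cov[name]
        data[name] = s_k * zsex + g_k * zage + noise(s_k * s_k * 0.25 + g_k * g_k)
    for name in SYMPTOM_PHENOTYPES:
        b_k = spec.b_paths.get(name, 0.0)
        d_k = spec.direct_paths.get(name, 0.0)
        s_k, g_k = cov[name]
        star = b_k * med_star + d_k * carrier + s_k * zsex + g_k * zage
        star = star + noise(b_k * b_k + d_k * d_k * var_c + s_k * s_k * 0.25 + g_k * g_k)
        data[name] = star
    data[MEDIATOR] = med_star
    data["rrs_brooding"] = 0.55 * med_star + noise(0.55**2)
    data["rrs_reflection"] = 0.45 * med_star + noise(0.45**2)

    frame = pd.DataFrame(data, index=pd.Index(g.sample_ids, name="iid"))
    for name in ALL_PHENOTYPES:
        mean, sd = PHENOTYPE_SCALE[name]
        frame[name] = mean + sd * frame[name]
    return frame[["sex", "age"] + ALL_PHENOTYPES]


def gen_scale_items(
    scores: np.ndarray, n_items: int, loading: float, rng
) -> np.ndarray:
    """Optional item-level mode: equal-loading items around a scale score.

    item_j = loading * z(score) + sqrt(1 - loading^2) * noise, giving a
    theoretical Cronbach alpha of k*l^2 / (1 + (k-1)*l^2) for k items.
    """
    z = _standardize(np.asarray(scores, dtype=float))
    e = rng.standard_normal((z.size, n_items))
    return loading * z[:, None] + np.sqrt(1.0 - loading**2) * e


def inject_qc_violations(
    g: GenotypeMatrix,
    n_low_maf: int = 0,
    n_hwe_violating: int = 0,
    n_high_missing_snps: int = 0,
    n_high_missing_samples: int = 0,
    seed: int = 0,
) -> tuple[GenotypeMatrix, dict]:
    """Return a copy of ``g`` with controlled QC violations and a manifest.

    Violations are injected into distinct non-focal SNPs: near-monomorphic
    columns (MAF ~ 1/(2n)), all-heterozygote columns (extreme HWE excess),
    columns with 15% missing calls, and sample rows with 20% missing calls.
    """
    rng = np.random.default_rng(seed)
    out = g.copy()
    n, m = out.n_samples, out.n_snps
    n_snp_targets = n_low_maf + n_hwe_violating + n_high_missing_snps
    eligible = np.flatnonzero(~out.snps.get("is_focal", pd.Series(False, index=out.snps.index)).to_numpy())
    if n_snp_targets > eligible.size:
        raise ValueError("more SNP violations requested than non-focal SNPs")
    if n_high_missing_samples > n:
        raise ValueError("more sample violations requested than samples")
    chosen = rng.choice(eligible, size=n_snp_targets, replace=False)
    low_idx = chosen[:n_low_maf]
    hwe_idx = chosen[n_low_maf : n_low_maf + n_hwe_violating]
    miss_idx = chosen[n_low_maf + n_hwe_violating :]

    for idx in low_idx:
        col = np.zeros(n)
        col[rng.integers(n)] = 1.0  # a single heterozygote
        out.dosage[:, idx] = col
    for idx in hwe_idx:
        out.dosage[:, idx] = 1.0  # every sample heterozygous
    for idx in miss_idx:
        rows = rng.choice(n, size=max(1, int(round(0.15 * n))), replace=False)
        out.dosage[rows, idx] = np.nan

    sample_rows = rng.choice(n, size=n_high_missing_samples, replace=False)
    clean_cols = np.setdiff1d(np.arange(m), chosen)
    for row in sample_rows:
        cols = rng.choice(clean_cols, size=max(1, int(round(0.2 * m))), replace=False)
        out.dosage[row, cols] = np.nan

    snp_ids = out.snp_ids
    manifest = {
        "low_maf": sorted(snp_ids[low_idx].tolist()),
        "hwe": sorted(snp_ids[hwe_idx].tolist()),
        "high_missing_snps": sorted(snp_ids[miss_idx].tolist()),
        "high_missing_samples": sorted(out.sample_ids[sample_rows].tolist()),
    }
    return out, manifest
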