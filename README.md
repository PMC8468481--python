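# genemediate

Gene-wide SNP association and mediation-discovery analysis for continuous
phenotypes: genotype quality control, kinship-corrected linear-mixed-model
scans, effective-test multiple-testing correction, Bayesian-network
relevance analysis, and structural-equation mediation with delta-method
indirect effects — all driven by a synthetic-data generator that encodes a
known genotype → mediator → outcome causal structure, so every stage is
testable end to end without access to individual-level cohort data.

The motivating design is a single-gene candidate study: a few hundred SNPs
in one gene region, a population cohort of several hundred adults
(including relatives), and a battery of 18 continuous phenotypes — an
anthropometric measure (BMI), four cardiovascular risk scores
(Framingham-type), ten psychiatric symptom scale scores (BSI), and three
rumination scale scores (RRS). The scientific question: is a SNP's effect
on the psychiatric symptom scores transmitted *through* trait rumination
(an endophenotype), while its cardiovascular associations remain
independent of that pathway?

## The models

**Association scan.** Per phenotype `y` and SNP dosage `g`:

    y = W a + g b + u + e,    u ~ N(0, sg^2 K),  e ~ N(0, se^2 I)

with covariates `W` (sex, age, optionally the sibling rumination subscale
or the mediator) and `K` the genomic relationship matrix from standardized
dosages, estimated leave-one-chromosome-out (LOCO) so the tested gene's
chromosome never contaminates its own kinship correction. Variance
components are fit by REML through a single eigendecomposition of `K` and
1-D profile optimization over `delta = se^2/sg^2`; each SNP gets a 1-df Wald
test at the null-model `delta`.

**Multiple testing.** The effective number of independent tests `Meff` is
the smallest `j` such that the top `j` eigenvalues of the SNP correlation
matrix reach 99.5% of their total (the simpleM construction); the gene-wide
threshold is `alpha / (Meff × #phenotypes)`.

**Relevance network.** Phenotypes discretized to terciles plus binary sex
and carrier-coded SNPs enter a discrete Bayesian network scored by the
Cooper–Herskovits (Dirichlet(1,…,1)) marginal likelihood, with sex, age and
SNPs exogenous and at most 4 parents per node. Metropolis–Hastings
structure MCMC over add/delete/reverse edge moves (with the
neighborhood-size Hastings correction) yields posterior probabilities for
edges, undirected relations, and variable *categories* (is the SNP linked
to at least one rumination-family variable?). A posterior above 0.5 marks a
connection as more probable than not.

**Mediation SEM.** For a screened (SNP, mediator, outcome) triple the path
model regresses the mediator on the carrier indicator plus confounders and
each outcome on mediator + carrier + confounders (+ any genome principal
components correlated with it). The indirect effect is `a·b` with a
delta-method robust SE, standardized by the model-implied outcome SD;
model fit is summarized by `T = (n−1)F`, RMSEA, CFI and TLI. Outcomes are
classified as total mediation (indirect significant, direct not), partial,
or none.

**Power.** For an additive per-allele effect `beta` on a trait with SD
`sd_y`, the locus explains `v = 2·maf·(1−maf)·beta^2`, giving noncentrality
`lambda = n·R²/(1−R²)` with `R² = v/sd_y²` and two-sided normal-approximation
power.

## Worked example

```python
import numpy as np
from genemediate import mediation, qc, simulate

spec = simulate.SimulationSpec(
    n_samples=795, n_gene_snps=274, n_background_snps=2000, seed=0
)
g = simulate.gen_genotypes(spec)
phen = simulate.gen_phenotypes(g, spec)

clean, report = qc.run_qc(g, qc.QCConfig(), mode="unrelated")
print(f"QC: {g.n_samples} -> {clean.n_samples} samples")

focal = simulate.focal_snp_index(clean)
phen_u = phen.loc[clean.sample_ids].copy()
phen_u["carrier"] = mediation.dominant_code(clean.dosage[:, focal])
model = mediation.PathModelSpec(
    exposure="carrier", mediator="rrs_rumination",
    outcomes=["bsi_gsi", "bsi_depression", "bsi_anxiety"],
)
fit = mediation.fit_path_model(phen_u, model)
print(mediation.indirect_effects(fit).round(3).to_string(index=False))
print(mediation.mediation_verdict(fit)[["outcome", "verdict"]].to_string(index=False))
```

prints

```
QC: 795 -> 714 samples
       outcome  indirect    se     p
       bsi_gsi     0.115 0.057 0.043
bsi_depression     0.114 0.056 0.043
   bsi_anxiety     0.103 0.051 0.042
       outcome         verdict
       bsi_gsi total mediation
bsi_depression         partial
   bsi_anxiety total mediation
```

The unrelated-mode QC broke the cohort's 80 related pairs (plus a handful
of heterozygosity outliers), and the SEM recovered outcome-standardized
indirect effects of ~0.10–0.12 through rumination — the generator's true
values are `0.308 × b_k` (0.146 for the global severity index). With a
carrier frequency under 10% and ~714 samples the indirect test has only
moderate power, so single cohorts of this size sit near the significance
boundary (here one direct path fluctuated into "partial"); averaging over
many generated cohorts recovers the true effects tightly (see the
reproduction script below). The full pipeline — QC, LOCO scans, effective
tests, correlation screening, network relevance, SEM verdicts — runs from
one config via `genemediate run-all --seed 0 --out run/` or
`genemediate.pipeline.run_all`.

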