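# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the design decisions behind `genemediate`, in the package's own
terms. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. Synthetic cohort generator (`genemediate.simulate`)

The generator is the package's definition of its study conditions, not a
test convenience. Defaults describe a single-gene candidate study:

| parameter | default | meaning |
|---|---|---|
| `n_samples` | 795 | cohort size before sample QC |
| `n_gene_snps` | 274 | SNPs in the gene region (one chromosome) |
| `n_background_snps` | 2000 | SNPs on the other chromosomes, for kinship |
| `n_related_pairs` | 80 | pairs sharing one parental haplotype |
| `maf_range` | (0.01, 0.5) | admissible minor allele frequencies |
| `focal_maf` | 0.0489 | MAF of the causal (focal) SNP |
| `a_path` | 0.308 | carrier → mediator effect, in mediator SDs |
| `b_paths` | per outcome | mediator → symptom effects, SD/SD units |
| `direct_paths` | all 0 | carrier → outcome effects (full mediation) |

**Genotypes.** Each SNP is built from two independent haplotype draws per
person, so Hardy–Weinberg proportions hold marginally by construction.
Within an LD block the haplotype alleles come from a latent equicorrelated
Gaussian thresholded at `Phi^-1(maf)` (one MAF per block, so a `rho = 1`
block yields exactly duplicated dosage columns). The default block layout
cycles singleton / tight (`rho` 0.95) / moderate (0.8) / loose (0.6)
blocks; the focal SNP always occupies its own singleton block. The block
structure of real single-gene regions is not identifiable from published
summaries, so these are free parameters chosen to mix strong and weak LD.
Relatedness is gene-dropped: the second member of each related pair copies
the first member's entire first haplotype, giving expected PI_HAT ≈ 0.5
(kinship ≈ 0.25) without pedigree machinery. Empirical MAFs that fall below
the admissible minimum are re-drawn so that clean generated data pass the
QC MAF filter by construction.

**Phenotypes.** Sex is Bernoulli(1/2), age uniform on 20–80 years (a
deliberately simple adult-cohort stand-in). On a standardized scale:

    mediator* = a · carrier + s_m · sex_c + g_m · age_z + noise
    symptom_k* = b_k · mediator* + d_k · carrier + s_k · sex_c + g_k · age_z + noise
    cardio_j*  = s_j · sex_c + g_j · age_z + noise

Noise variances keep each starred variable near unit variance; each column
is then mapped to a target mean/SD typical of its phenotype class (BMI
~27.4 ± 5.0; risk scores in percent; symptom scales on 0–4; rumination
scales on 1–4), so power calculations against those SDs stay comparable.
The brooding and reflection scores are generated as noisy loadings on the
rumination mediator (0.55 and 0.45). The negative partial correlation
between brooding and reflection residuals seen in real questionnaire data
is *not* reproduced — the two subscales here are positively related through
their common factor; nothing downstream depends on that sign.

**Path-coefficient convention.** `a_path` is the effect of carrier status
(0/1) in mediator-SD units, and `b_paths` are per-mediator-SD effects in
outcome-SD units. Under this convention the outcome-SD-standardized
indirect effect estimated by the SEM equals `a · b_k` exactly, which is the
quantity the recovery checks assert. The default `b_paths` for the eight
"mediated" symptom scores are the targeted standardized indirect effects
divided by `a = 0.308` (e.g. 0.474 for the global severity index); the two
remaining symptom scores get `b ≈ 0.36–0.37`, consistent with their
mediator correlations.

**What passing tests do and do not show.** The generator produces Gaussian
phenotypes with exact linear structure, a single causal SNP, and
independent noise. Passing recovery tests therefore demonstrates the
*estimators* are correct and calibrated under the assumed model; they say
nothing about robustness to skewed scale scores, floor effects in symptom
inventories, genotyping artifacts beyond the injected kinds, or model
misspecification in real cohorts.

## 2. Quality control (`genemediate.qc`)

Order of operations: (1) biallelic SNVs with MAF ≥ 0.01; (2) iterative
missingness filtering at thresholds 0.1 → 0.05 → 0.01, variants before
samples at each threshold; (3) Hardy–Weinberg exact-test filter at
p < 1e-5 (plain two-sided exact test summing outcomes no more probable than
observed, conditional on allele counts; no mid-p); the SNP set is final
here. Sample-level filters then operate on an LD-pruned SNP subset
(sliding window 1500, step 150, r² ≤ 0.2): optional IBD relatedness
filtering at PI_HAT > 0.1875 (unrelated mode), then heterozygosity-F
outliers beyond 3 SD of the sample mean.

Numerical/tie-break choices, all deterministic:

- LD pruning resolves the lexicographically first violating pair per
  window by removing the higher-missingness member, ties by later
  position; window sweeps repeat until a full pass removes nothing.
- IBD pair resolution removes the higher-missingness member, ties by
  keeping the earlier sample id; pairs are processed in decreasing PI_HAT.
- PI_HAT uses PLINK-style method-of-moments on IBS counts with asymptotic
  expected IBS probabilities at the sample allele frequencies; the
  finite-sample allele-count corrections are omitted. The IBD-state
  estimates are left unclamped (their noise stays symmetric around zero
  for unrelated pairs) and only the final PI_HAT is clamped to [0, 1];
  clamping the states individually would bias PI_HAT upward by roughly
  half its sampling SD. Precision scales as 1/sqrt(#markers): with ~1000+
  pruned markers the unrelated-pair SD is a few percent, so the default
  threshold cleanly separates first-degree pairs.
- Allele frequencies for the F statistic and for IBD are recomputed on the
  current (post-missingness, and in unrelated mode post-IBD) sample set,
  matching the stated step order; whether real pipelines compute the
  heterozygosity mean/SD before or after relatedness removal is ambiguous —
  here it is after.
- Missing dosages are a NaN sentinel; QC never imputes.

Idempotence caveat: the SNP-level filters are exactly idempotent. The
heterozygosity cut is a relative (mean ± 3 SD) criterion, so rerunning QC
on its own output can, on unlucky data, trim a further ~0.3% of samples;
the tests assert exact SNP idempotence and bounded sample idempotence.

## 3. Mixed-model scan (`genemediate.lmm`)

`K = ZZ'/M` from column-standardized, mean-imputed dosages, LOCO per tested
chromosome. REML via one eigendecomposition of `K`: with `K = U S U'`, the
rotated model has independent errors with variances `sg²(s_i + delta)`;
`delta` is profiled on 50 log-spaced points in [1e-5, 1e5] followed by
bounded scalar minimization to 1e-6 in log delta. The restricted likelihood
includes the `log|W'W|` term so it is invariant to covariate rescaling, and
the spectral expression is verified against a dense GLS oracle to 1e-8.

SNP tests append the (mean-imputed, additive or dominant-coded) dosage to
the fixed effects at the null `delta` (the population-parameters-
previously-determined convention; no per-SNP variance refit), re-estimate
the residual scale with the SNP included, and report a 1-df Wald p-value.
With `K = I` this reproduces OLS coefficients and standard errors exactly,
with a normal instead of t reference. Monomorphic and collinear SNPs yield
flagged records rather than tests. REML + Wald was chosen over ML + LRT as
the standard, fast combination that admits the exact OLS cross-check.

## 4. Effective tests (`genemediate.meff`)

Dosage (composite) correlations, pairwise complete. Eigenvalues are clipped
at zero before cumulative sums; `Meff` is the smallest `j` reaching 99.5%
of the spectrum mass — the published simpleM cutoff, kept fixed. The
threshold is `alpha / (Meff × #phenotype models)`.

## 5. Bayesian-network relevance (`genemediate.bayesnet`)

Families are scored by the Dirichlet(1,…,1) (Cooper–Herskovits/K2)
marginal likelihood computed with log-gamma; the structure prior is uniform
over admissible DAGs. Constraints: exogenous variables (sex, age, SNPs)
accept no incoming edges and no edges among themselves; at most 4 parents
per node. One caveat documented deliberately: the K2 score is *not*
score-equivalent across Markov-equivalent DAGs (for two binary variables
the log-score gap is `log((m0+1)(m1+1)) − log((n0+1)(n1+1))` in the
marginal counts), so edge directions within an equivalence class carry
prior-dependent information; relevance conclusions use the direction-free
relation posterior.

MCMC: Metropolis–Hastings over single-edge add/delete/reverse moves,
proposal uniform over the admissible move set with the `|N(G)|/|N(G')|`
Hastings correction; acyclicity via descendant sets per step. Desk-scale
defaults are 10^4 burn-in / 10^5 samples with thinning 10 (the pipeline
uses 5·10^3 / 2·10^4 to keep a 22-variable run interactive); chain lengths
of 10^6 / 5·10^6 are accepted via configuration. Thinned samples are stored
as packed bitsets (~tens of bytes each) so category posteriors can be
evaluated after the run for arbitrary variable groups.

"Categorical posterior" is interpreted as adjacency: the posterior
probability that the target connects (either direction) to at least one
category member. A Markov-blanket-membership variant is available behind
`method="markov_blanket"`, since both definitions appear in the multilevel-
analysis literature and the choice is not decidable from published
descriptions; the relevance filter applies a strict `> 0.5` rule either way.
Correctness is anchored to exhaustive DAG enumeration on 3–5 variable
systems (25 DAGs at V=3, 543 at V=4), including category posteriors.

## 6. Mediation SEM (`genemediate.mediation`)

Screening requires both prerequisites at `p ≤ 0.05`: the mediator–outcome
correlation (on sex/age-residualized mediator scores) and a shared
significant SNP. Genome PCs are eigenvectors of the standardized-genotype
sample covariance (sign fixed by the largest-magnitude loading), computed
on unrelated samples; a PC joins an outcome's equation iff correlated at
`p ≤ 0.05`.

The path model is recursive: mediator on carrier + sex + age; each outcome
on mediator + carrier + sex + age (+ selected PCs). Estimation is
equation-wise OLS — exact ML when the freed residual covariances span the
outcome block and the equations share regressors — followed by a
Nelder–Mead polish of the normal-theory discrepancy
`F = log|Sigma(theta)| + tr(S Sigma^-1) − log|S| − p` whenever the model is
over-identified (df > 0), with the exogenous covariance block held
saturated at `S_xx`. `T = (n−1)·F_min` with `S` computed with the n−1
denominator; this multiplier choice is calibrated so the printed-precision
RMSEA check (T = 20.184, df = 14, n = 634 → 0.026) holds under either n or
n−1 rounding. Residual covariances among outcome equations are freed by
default (the model is then saturated and T = 0); fixing them (as real
reports with positive df do) yields positive df through the same formulas.
The exact free-parameter inventory behind any particular published df is
not recoverable from text, so the module reports df from its own
specification.

Robust ("MLR-style") coefficient covariance is the HC0 sandwich on the
stacked per-observation moment conditions of all equations, which supplies
the cross-equation `cov(a, b)` the delta method needs:
`Var(ab) = b²V_a + a²V_b + 2ab·Cov(a,b)`. A Satorra–Bentler-type scaling of
T is *not* applied (the fit statistic is used only through the index
formulas). Indirect and direct effects are standardized by the
model-implied outcome SD. Fit indices: RMSEA = sqrt(max(T−df,0)/(df(n−1))),
CFI and TLI against the diagonal (independence) baseline.

Verdicts per outcome: "total mediation" (indirect p ≤ 0.05, direct
p > 0.05), "partial" (both ≤ 0.05), "none" (indirect p > 0.05). Because
each true-zero direct path still rejects at its nominal 5% rate, a cohort
with several outcomes is expected to show an occasional "partial" even
under pure full mediation; aggregate checks therefore test the direct-path
rejection *rate*, not its absence.

## 7. Power (`genemediate.power`)

Two-sided normal approximation with both tail terms retained,
`lambda = n·R²/(1−R²)`, `R² = 2·maf·(1−maf)·beta²/sd_y²` where `sd_y` is the
**total** outcome SD — the convention that reproduces the printed minimum
power anchors (5.05% for an SD-5.034 outcome, 9.67% for SD 0.503 at
n = 795, MAF 0.01, beta 0.08) and is therefore the package's calibration
anchor. Display is percent to 2 decimals, capped at 99.99. `R² ≥ 1` returns
power 1 with a warning.

## 8. Pipeline, seeds, and problem sizes

`pipeline.run_all` executes simulate → QC (both modes) → LOCO scan →
Meff/threshold → residualized correlation screen → candidate screening →
mediator-adjusted scan → network relevance → SEM verdicts, writing
TSV/JSON artifacts and a manifest with SHA-256 hashes; per-stage seeds fan
out from the run seed via a `SeedSequence`, each below 2^31, so stages are
independently reproducible.

Problem sizes in the test suite and the acceptance script are the
package's own scaled-down study conditions: 200 replicate cohorts at
n = 634 for mediation recovery (coverage asserted at 95% ± 4%), 2000
permuted null SNPs for type-I calibration (± 0.013), 10^5 MCMC samples
against enumeration (± 0.02), and n = 2000 with a common focal variant
(MAF 0.25, a = 0.5) for the mediator-adjustment demonstration — the last
chosen by a pre-hoc power calculation so the unadjusted association is
detected with >99.9% probability while the adjusted one is null. Rare-
carrier conditions (MAF 0.0489) at single-cohort scale intentionally sit
near the significance boundary; conclusions at that scale are only made in
replicate aggregate.

## 9. Known limitations

- The latent-Gaussian LD model controls haplotype tetrachoric correlation;
  realized dosage r² is somewhat below the latent `rho` for rare alleles.
- PI_HAT omits finite-sample frequency corrections and degrades below a
  few hundred markers.
- The SEM supports only observed-variable recursive path models (no latent
  measurement models, no categorical-endogenous estimators).
- The Bayesian network assumes complete cases and discretized variables;
  posterior probabilities inherit the K2 prior's direction asymmetry.
- The power module covers the continuous-trait additive model only.
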