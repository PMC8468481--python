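"""End-to-end orchestration: simulate/load -> QC -> scans -> Meff ->
screening -> Bayesian-network relevance -> SEM mediation.

Each stage derives its own seed from the run seed, writes its artifacts as
TSV/JSON under the output directory, and is recorded in a manifest; a
failure in a later stage leaves earlier artifacts in place.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import bayesnet, lmm, mediation, meff, phenotypes, qc, simulate
from .plink import write_plink

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "genemediate_run"
    simulation: dict = field(default_factory=dict)  # SimulationSpec overrides
    qc: dict = field(default_factory=dict)  # QCConfig overrides
    alpha: float = 0.05
    bmla_burn_in: int = 5_000
    bmla_samples: int = 20_000
    bmla_thin: int = 10
    bmla_max_parents: int = 4
    n_pcs: int = 10
    mediator: str = simulate.MEDIATOR

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def stage_seeds(seed: int, n: int = 16) -> list[int]:
    """Fan one run seed out to independent per-stage seeds (< 2^31)."""
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n) % (2**31)]


def _write(df: pd.DataFrame, path: str) -> str:
    df.to_csv(path, sep="\t", index=False)
    return path


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def default_model_specs(mediator_adjusted: bool = False, mediator: str = simulate.MEDIATOR):
    """The 18 per-phenotype model specifications.

    Sex and age always covary; the sibling rumination subscale covaries the
    brooding/reflection models; secondary analyses add the mediator.
    """
    specs = []
    for name in simulate.ALL_PHENOTYPES:
        cov = ["sex", "age"]
        if name == "rrs_brooding":
            cov.append("rrs_reflection")
        elif name == "rrs_reflection":
            cov.append("rrs_brooding")
        med = None
        if mediator_adjusted and name not in simulate.RUMINATION_PHENOTYPES:
            med = mediator
        specs.append(lmm.LMMModelSpec(outcome=name, covariates=cov, mediator=med))
    return specs


def run_all(config: RunConfig) -> dict:
    """Execute the full analysis; returns the run manifest."""
    os.makedirs(config.out_dir, exist_ok=True)
    seeds = stage_seeds(config.seed)
    manifest: dict = {"seed": config.seed, "stage_seeds": seeds, "stages": {}, "artifacts": {}}

    def record(stage: str, **info):
        manifest["stages"][stage] = info
        _dump_manifest(manifest, config.out_dir)

    # ---- stage 1: synthetic cohort -------------------------------------
    sim_spec = simulate.SimulationSpec(seed=seeds[0], **config.simulation)
    g = simulate.gen_genotypes(sim_spec)
    phen = simulate.gen_phenotypes(g, sim_spec)
    prefix = os.path.join(config.out_dir, "cohort")
    write_plink(g, prefix)
    phen_path = os.path.join(config.out_dir, "phenotypes.csv")
    phen.to_csv(phen_path)
    manifest["artifacts"]["phenotypes"] = _sha256(phen_path)
    record("simulate", n_samples=g.n_samples, n_snps=g.n_snps, spec=str(sim_spec))

    # ---- stage 2: quality control --------------------------------------
    qc_config = qc.QCConfig(**config.qc)
    g_all, report_all = qc.run_qc(g, qc_config, mode="all")
    g_unrel, report_unrel = qc.run_qc(g, qc_config, mode="unrelated")
    report_all.to_json(os.path.join(config.out_dir, "qc_all.json"))
    report_unrel.to_json(os.path.join(config.out_dir, "qc_unrelated.json"))
    record(
        "qc",
        n_samples_all=g_all.n_samples,
        n_samples_unrelated=g_unrel.n_samples,
        n_snps=g_all.n_snps,
    )

    # ---- stage 3: primary LMM scan (LOCO kinship) ----------------------
    gene_idx = np.flatnonzero(
        (g_all.snps["chrom"] == sim_spec.gene_chromosome).to_numpy()
    )
    assoc = lmm.scan(
        g_all, phen, default_model_specs(), loco=True, snp_idx=gene_idx, alpha=config.alpha
    )
    assoc_path = _write(assoc, os.path.join(config.out_dir, "associations.tsv"))
    _write(lmm.manhattan_table(assoc), os.path.join(config.out_dir, "manhattan.tsv"))
    manifest["artifacts"]["associations"] = _sha256(assoc_path)
    record("scan", n_records=len(assoc))

    # ---- stage 4: effective tests and threshold ------------------------
    corr = meff.snp_correlation_matrix(g_all.subset(snp_idx=gene_idx))
    eff = meff.meff_gao(corr)
    threshold = meff.bonferroni_threshold(eff.meff, len(simulate.ALL_PHENOTYPES), config.alpha)
    with open(os.path.join(config.out_dir, "meff.json"), "w") as fh:
        json.dump(
            {"M": eff.M, "meff": eff.meff, "C": eff.C, "threshold": threshold}, fh, indent=2
        )
    record("meff", M=eff.M, meff=eff.meff, threshold=threshold)

    # ---- stage 5: residualized correlation screen ----------------------
    resid = phenotypes.residualize(
        phen, phenotypes.ResidualSpec(target=config.mediator, covariates=["sex", "age"])
    )
    outcome_cols = simulate.CARDIO_PHENOTYPES + simulate.SYMPTOM_PHENOTYPES
    corr_table = phenotypes.correlation_screen(
        resid.rename(config.mediator).to_frame(), phen[outcome_cols], alpha=config.alpha
    )
    _write(corr_table, os.path.join(config.out_dir, "correlations.tsv"))
    record("correlations", n_significant=int(corr_table["significant"].sum()))

    # ---- stage 6: mediation candidate screening ------------------------
    candidates = mediation.screen_candidates(corr_table, assoc, alpha=config.alpha)
    cand_df = pd.DataFrame([dataclasses.asdict(c) for c in candidates])
    _write(cand_df, os.path.join(config.out_dir, "candidates.tsv"))
    record("screening", n_candidates=len(candidates))

    focal = simulate.focal_snp_index(g_all)
    focal_id = g_all.snps["snp"].iloc[focal]

    # ---- stage 7: mediator-adjusted secondary scan ---------------------
    assoc_adj = lmm.scan(
        g_all,
        phen,
        default_model_specs(mediator_adjusted=True, mediator=config.mediator),
        loco=True,
        snp_idx=np.array([focal]),
        alpha=config.alpha,
    )
    _write(assoc_adj, os.path.join(config.out_dir, "associations_adjusted.tsv"))
    record("adjusted_scan", n_records=len(assoc_adj))

    # ---- stage 8: Bayesian-network relevance ---------------------------
    phen_unrel = phen.loc[g_unrel.sample_ids]
    disc = {"sex": phen_unrel["sex"].astype(int).to_numpy()}
    disc["age"] = phenotypes.discretize_terciles(phen_unrel["age"].to_numpy(), "age")
    for col in simulate.ALL_PHENOTYPES:
        disc[col] = phenotypes.discretize_terciles(phen_unrel[col].to_numpy(), col)
    focal_u = simulate.focal_snp_index(g_unrel)
    carrier_u = mediation.dominant_code(g_unrel.dosage[:, focal_u])
    disc[focal_id] = np.nan_to_num(carrier_u, nan=0.0).astype(int)
    disc_df = pd.DataFrame(disc, index=phen_unrel.index)
    dataset = bayesnet.DiscreteDataset.from_dataframe(disc_df)
    constraints = bayesnet.StructureConstraints(
        exogenous=frozenset({"sex", "age", focal_id}),
        max_parents=config.bmla_max_parents,
    )
    post = bayesnet.structure_mcmc(
        dataset,
        constraints,
        burn_in=config.bmla_burn_in,
        n_samples=config.bmla_samples,
        thin=config.bmla_thin,
        seed=seeds[7],
    )
    relevance = bayesnet.relevance_filter(
        post,
        [
            (focal_id, config.mediator),
            (focal_id, simulate.RUMINATION_PHENOTYPES),
            (focal_id, simulate.SYMPTOM_PHENOTYPES),
            (focal_id, simulate.CARDIO_PHENOTYPES[1:]),  # risk-score category
        ],
    )
    _write(relevance, os.path.join(config.out_dir, "bmla_relevance.tsv"))
    edge_df = pd.DataFrame(post.edge, index=post.names, columns=post.names)
    edge_df.to_csv(os.path.join(config.out_dir, "bmla_edges.tsv"), sep="\t")
    record(
        "bmla",
        acceptance_rate=post.acceptance_rate,
        relevant=relevance[relevance["relevant"]]["other"].tolist(),
    )

    # ---- stage 9: SEM mediation ---------------------------------------
    sem_data = phen_unrel.copy()
    sem_data["carrier"] = carrier_u
    pcs = mediation.genome_pcs(g_unrel, k=config.n_pcs)
    mediated_outcomes = [
        o for o in simulate.SYMPTOM_PHENOTYPES
        if any(c.outcome == o and c.mediator == config.mediator for c in candidates)
    ] or simulate.SYMPTOM_PHENOTYPES
    pc_sel = mediation.select_pc_covariates(
        pcs, sem_data[mediated_outcomes], alpha=config.alpha
    )
    sem_data = sem_data.join(pcs.components)
    spec = mediation.PathModelSpec(
        exposure="carrier",
        mediator=config.mediator,
        outcomes=mediated_outcomes,
        pc_assignments={k: v for k, v in pc_sel.items() if v},
    )
    fit = mediation.fit_path_model(sem_data, spec)
    verdict = mediation.mediation_verdict(fit, adjusted_scan=assoc_adj, alpha=config.alpha)
    _write(verdict, os.path.join(config.out_dir, "mediation_verdict.tsv"))
    with open(os.path.join(config.out_dir, "sem_fit.json"), "w") as fh:
        json.dump(
            {
                "n": fit.n,
                "T": fit.T,
                "df": fit.df,
                "p": fit.p,
                "rmsea": fit.rmsea,
                "cfi": fit.cfi,
                "tli": fit.tli,
            },
            fh,
            indent=2,
        )
    record(
        "mediation",
        n=fit.n,
        rmsea=fit.rmsea,
        verdicts={r["outcome"]: r["verdict"] for _, r in verdict.iterrows()},
    )

    _dump_manifest(manifest, config.out_dir)
    return manifest


def _dump_manifest(manifest: dict, out_dir: str) -> None:
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
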