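"""End-to-end orchestration: simulate -> qc -> prs -> concordance -> assoc.

Each stage writes its outputs as TSV under the run directory and the run
closes with a JSON manifest listing every file with a content hash, the
full config echo and per-stage status.  A single master seed is expanded
into per-stage substreams so stages replay identically in isolation.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import association as assoc_mod
from . import concordance as conc_mod
from . import io as io_mod
from . import prs as prs_mod
from . import qc as qc_mod
from . import simulate as sim_mod
from .datatypes import CohortTable, DxprsError, GenotypeMatrix, SummaryStats

log = logging.getLogger(__name__)

STAGES = ("simulate", "qc", "prs", "concordance", "assoc")

#: Demonstration study conditions for `run-all`: a case-enriched sampling
#: frame (as in clinical ascertainment) with a well-powered training GWAS,
#: sized to finish in minutes on one CPU.
DEMO_PROFILE = dict(
    n_individuals=600,
    h2_prs=0.2,
    K_lifetime=0.35,
    n_train=100_000,
)


class PipelineError(DxprsError):
    pass


@dataclass
class RunConfig:
    """Everything one reproducible run needs."""

    out_dir: Path = Path("dxprs_run")
    seed: int = 0
    stages: tuple = STAGES
    sim: sim_mod.SimConfig = None
    qc: qc_mod.QCThresholds = field(default_factory=qc_mod.QCThresholds)
    prs: prs_mod.PRSConfig = field(default_factory=prs_mod.PRSConfig)
    liability: assoc_mod.LiabilityParams = field(default_factory=assoc_mod.LiabilityParams)
    genotypes: Path | None = None          # pre-existing inputs instead of simulate
    genotype_format: str = "dosage_tsv"
    sumstats: Path | None = None
    cohort: Path | None = None
    reference_r2_table: Path | None = None  # optional background for the r2 report

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if self.sim is None:
            self.sim = sim_mod.SimConfig(seed=self.seed)
        for p in (self.genotypes, self.sumstats, self.cohort, self.reference_r2_table):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)

    def echo(self) -> dict:
        return dataclasses.asdict(self)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages in dependency order.

    Returns the manifest dict.  A failing stage leaves earlier outputs in
    place, is recorded in the manifest, and raises PipelineError.
    """
    out = cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    status: dict[str, str] = {}
    ctx: dict = {}
    failure = None
    for stage in STAGES:
        if stage not in cfg.stages:
            status[stage] = "skipped"
            continue
        try:
            _STAGE_FUNCS[stage](cfg, ctx, outputs)
            status[stage] = "ok"
        except Exception as exc:
            status[stage] = f"failed: {exc}"
            failure = exc
            log.error("stage %s failed: %s", stage, exc)
            break
    manifest_path = out / "manifest.json"
    io_mod.write_manifest(manifest_path, outputs, cfg.echo(), status)
    if failure is not None:
        raise PipelineError(f"pipeline failed at stage marked in {manifest_path}") from failure
    return {"manifest": str(manifest_path), "stages": status, "outputs": {k: str(v) for k, v in outputs.items()}}


def _stage_simulate(cfg: RunConfig, ctx: dict, outputs: dict) -> None:
    out = cfg.out_dir
    if cfg.genotypes is not None:
        ctx["G"] = io_mod.read_genotypes(cfg.genotypes, format=cfg.genotype_format)
        ctx["ss"] = io_mod.read_sumstats(cfg.sumstats)
        ctx["cohort"] = io_mod.read_cohort(cfg.cohort)
        return
    G, state, ss, cohort = sim_mod.simulate_cohort(cfg.sim)
    ctx.update(G=G, state=state, ss=ss, cohort=cohort)
    io_mod.write_dosage_tsv(G, out / "genotypes.tsv")
    io_mod.write_sumstats(ss, out / "sumstats.tsv")
    io_mod.write_cohort(cohort, out / "cohort.tsv")
    outputs["genotypes"] = out / "genotypes.tsv"
    outputs["sumstats"] = out / "sumstats.tsv"
    outputs["cohort"] = out / "cohort.tsv"


def _stage_qc(cfg: RunConfig, ctx: dict, outputs: dict) -> None:
    out = cfg.out_dir
    G: GenotypeMatrix = ctx["G"]
    kept, fails = qc_mod.snp_qc(G, cfg.qc)
    pruned_idx = qc_mod.ld_prune(kept, cfg.qc)
    G_pruned = kept.subset_variants(pruned_idx)
    A = qc_mod.relatedness_matrix(G_pruned)
    kept_ind, rel_log = qc_mod.relatedness_filter(A, cfg.qc, seed=cfg.seed)
    G_rel = G_pruned.subset_individuals(kept_ind)
    pca = qc_mod.pca_cluster(G_rel, cfg.qc)
    final_ids = [G_rel.individual_ids[i] for i in pca.kept]
    ctx["G_qc"] = kept.subset_individuals(kept_ind).subset_individuals(pca.kept)
    ctx["G_pruned"] = G_rel.subset_individuals(pca.kept)
    ctx["pcs"] = pd.DataFrame(
        pca.scores[pca.kept],
        columns=[f"PC{k + 1}" for k in range(pca.scores.shape[1])],
    ).assign(individual_id=final_ids)
    fails.to_csv(out / "variant_exclusions.tsv", sep="\t", index=False)
    rel_log.to_csv(out / "relatedness_removals.tsv", sep="\t", index=False)
    ctx["pcs"].to_csv(out / "pc_scores.tsv", sep="\t", index=False)
    pd.Series(final_ids, name="individual_id").to_csv(out / "kept_individuals.tsv", sep="\t", index=False)
    pd.Series(kept.variants["variant_id"], name="variant_id").to_csv(out / "kept_variants.tsv", sep="\t", index=False)
    for name in ("variant_exclusions", "relatedness_removals", "pc_scores", "kept_individuals", "kept_variants"):
        outputs[name] = out / f"{name}.tsv"


def _stage_prs(cfg: RunConfig, ctx: dict, outputs: dict) -> None:
    out = cfg.out_dir
    G: GenotypeMatrix = ctx.get("G_qc", ctx["G"])
    ss: SummaryStats = ctx["ss"]
    ss_f = prs_mod.filter_sumstats(ss, cfg.prs)
    ss_c, skipped = prs_mod.clump(ss_f, G, cfg.prs)
    vec = prs_mod.score(G, ss_c, cfg.prs)
    ctx["prs"] = vec
    df = pd.DataFrame({"individual_id": vec.individual_ids, "raw": vec.raw, "z": vec.z})
    df.to_csv(out / "prs.tsv", sep="\t", index=False)
    pd.Series(ss_c.table["variant_id"], name="index_variant").to_csv(out / "clump_index.tsv", sep="\t", index=False)
    import json

    with open(out / "prs_config.json", "w") as fh:
        json.dump({**dataclasses.asdict(cfg.prs), "skipped": skipped + vec.skipped}, fh, indent=2, default=str)
    outputs["prs"] = out / "prs.tsv"
    outputs["clump_index"] = out / "clump_index.tsv"
    outputs["prs_config"] = out / "prs_config.json"


def _stage_concordance(cfg: RunConfig, ctx: dict, outputs: dict) -> None:
    out = cfg.out_dir
    cohort: CohortTable = ctx["cohort"]
    t3 = conc_mod.ppv_table(cohort)
    t3.to_csv(out / "report_selfreport_ppv.tsv", sep="\t", index=False)
    outputs["report_selfreport_ppv"] = out / "report_selfreport_ppv.tsv"
    t4 = medical_record_report(cohort, cfg.liability.pi_point)
    t4.to_csv(out / "report_record_predictive_values.tsv", sep="\t", index=False)
    outputs["report_record_predictive_values"] = out / "report_record_predictive_values.tsv"
    ctx["table3"] = t3
    ctx["table4"] = t4


def medical_record_report(cohort: CohortTable, pi: float) -> pd.DataFrame:
    """Predictive values of lifetime self-report for a record diagnosis,
    with both unadjusted and prevalence-restated PPV/NPV."""
    tab = conc_mod.build_contingency(
        cohort, "self_report_lifetime", {"SZ"}, "medical_record", {"SZ", "SA_D"},
        restrict_to_index_positive=False,
    )
    pv = conc_mod.predictive_values(tab, prevalence_pi=pi)
    return pd.DataFrame(
        [
            {
                "tp": tab.tp, "fp": tab.fp, "fn": tab.fn, "tn": tab.tn,
                "ppv": pv.ppv, "npv": pv.npv,
                "sensitivity": pv.sensitivity, "specificity": pv.specificity,
                "ppv_adjusted": pv.ppv_adjusted, "npv_adjusted": pv.npv_adjusted,
                "prevalence": pi,
            }
        ]
    )


def _stage_assoc(cfg: RunConfig, ctx: dict, outputs: dict) -> None:
    out = cfg.out_dir
    cohort: CohortTable = ctx["cohort"]
    vec: prs_mod.PRSVector = ctx["prs"]
    lp = cfg.liability
    groups = sim_mod.pathway_groups(cohort)
    id_pos = {iid: k for k, iid in enumerate(vec.individual_ids)}
    parts = cohort.participants.set_index("participant_id")

    def design(ids):
        ids = [i for i in ids if i in id_pos and i in parts.index]
        z = np.array([vec.z[id_pos[i]] for i in ids])
        sub = parts.loc[ids]
        male = sub["sex"].map({"male": 1.0, "female": 0.0}).to_numpy(float)
        yob = sub["year_of_birth"].to_numpy(float)
        # centred decades keep the Newton steps well conditioned
        yob = (yob - yob.mean()) / 10.0
        return ids, z, np.column_stack([male, yob])

    # Table-5-shaped: PRS case/control association per diagnosis definition
    rows = []
    controls = groups["controls"]
    definitions = {
        "self_report_lifetime": cohort.positives("self_report_lifetime", {"SZ", "SA_D"}),
        "research_interview": cohort.positives("research_interview", {"SZ", "SA_D"}),
        "medical_record": cohort.positives("medical_record", {"SZ", "SA_D"}),
    }
    for label, cases in definitions.items():
        if not cases or not controls:
            continue
        ids, z, X = design(list(cases) + list(controls))
        y = np.array([1.0 if i in cases else 0.0 for i in ids])
        if np.unique(y).size < 2:
            continue
        fit = assoc_mod.fit_logistic(y, np.column_stack([z, X]), ["prs_z", "male", "yob"])
        orr, lo, hi, p = fit.odds_ratio("prs_z")
        r2o, r2l, se = assoc_mod.variance_explained(y, X, z, lp, n_boot=100, seed=cfg.seed)
        rows.append(
            {
                "definition": label, "n_cases": int(y.sum()), "n_controls": int((1 - y).sum()),
                "OR": orr, "ci_low": lo, "ci_high": hi, "p": p,
                "r2_obs": r2o, "r2_liab": r2l, "se": se,
                "AUC": assoc_mod.auc(z, y),
            }
        )
    t5 = pd.DataFrame(rows)
    t5.to_csv(out / "report_prs_by_definition.tsv", sep="\t", index=False)
    outputs["report_prs_by_definition"] = out / "report_prs_by_definition.tsv"
    ctx["table5"] = t5

    # phenotype differences (self-report-only vs reference diagnosis)
    pheno_rows = []
    if groups["self_report_only"] and groups["reference"]:
        res = assoc_mod.compare_phenotypes(cohort, groups["self_report_only"], groups["reference"])
        pheno_rows = [
            {"phenotype": k, "OR": r.odds_ratio, "ci_low": r.ci_low, "ci_high": r.ci_high, "p": r.p, "n": r.n}
            for k, r in res.items()
        ]
    pd.DataFrame(pheno_rows).to_csv(out / "report_phenotype_differences.tsv", sep="\t", index=False)
    outputs["report_phenotype_differences"] = out / "report_phenotype_differences.tsv"

    # PRS by pathway group (figure data) + group-difference test
    fig3 = []
    for gname in ("self_report_only", "reference", "controls"):
        for i in groups[gname]:
            if i in id_pos:
                fig3.append({"group": gname, "individual_id": i, "prs_z": vec.z[id_pos[i]]})
    pd.DataFrame(fig3).to_csv(out / "report_prs_by_group.tsv", sep="\t", index=False)
    outputs["report_prs_by_group"] = out / "report_prs_by_group.tsv"

    # liability-r2 juxtaposition (figure data), optional reference table
    fig4 = t5[["definition", "r2_liab"]].assign(source="this_run") if len(t5) else pd.DataFrame(
        columns=["definition", "r2_liab", "source"]
    )
    if cfg.reference_r2_table is not None:
        ref = pd.read_csv(cfg.reference_r2_table, sep="\t")
        ref = ref.assign(source="reference")[["definition", "r2_liab", "source"]]
        fig4 = pd.concat([fig4, ref], ignore_index=True)
    fig4.to_csv(out / "report_r2_comparison.tsv", sep="\t", index=False)
    outputs["report_r2_comparison"] = out / "report_r2_comparison.tsv"


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "prs": _stage_prs,
    "concordance": _stage_concordance,
    "assoc": _stage_assoc,
}
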