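"""Synthetic liability-threshold cohort generator.

Generates every input the pipeline consumes with the statistical
structure the analysis assumes: biallelic genotypes with
compound-symmetry LD blocks, training-sample summary statistics with
sampling noise, binary case status from a Gaussian liability threshold at
lifetime risk K, three partially overlapping diagnosis sources with
configurable capture and misclassification rates, covariates with group
offsets, and per-case endorsement/admission counts.

Default pathway rates emulate a clinically-ascertained recruitment in
which self-reporters proceed to a research interview that confirms
schizophrenia 70% of the time, widening to 81% with schizoaffective
depressed type and 87% with any psychotic disorder.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

from .datatypes import (
    PARTICIPANT_COLUMNS,
    RECORD_COLUMNS,
    SUMSTATS_COLUMNS,
    VARIANT_COLUMNS,
    CohortTable,
    GenotypeMatrix,
    SummaryStats,
)

CONFUSION_CATEGORIES = ("SZ", "SA_D", "OTHER_PSYCHOTIC", "MOOD")

# substream labels so stages can be re-run in isolation reproducibly
_STREAM = {"genotypes": 1, "phenotype": 2, "sumstats": 3, "pathways": 4, "covariates": 5}


@dataclass
class PathwayParams:
    """Capture/misclassification rates for the three diagnosis sources.

    ``research_confusion`` rows (true category SZ, SA_D) give the
    research-interview category distribution for interviewed cases; the
    default SZ row reproduces a 0.70/0.81/0.87 concordance ladder in
    expectation.  ``liability_slope`` > 0 couples record capture,
    endorsement repetition, admission intensity and primary coding to the
    case's liability quantile (severity mode); 0 leaves pathways
    independent of liability.
    """

    p_record_given_case: float = 0.6
    p_selfreport_given_record: float = 0.8
    p_selfreport_given_no_record: float = 0.5
    research_confusion: dict = field(
        default_factory=lambda: {
            "SZ": (0.70, 0.11, 0.06, 0.13),
            "SA_D": (0.10, 0.70, 0.10, 0.10),
        }
    )
    false_selfreport_rate: float = 0.005
    p_current_given_lifetime: float = 0.875
    p_opinion_given_lifetime: float = 0.37
    p_second_endorsement: float = 0.35
    admission_lambda: float = 1.5
    p_primary_admission: float = 0.6
    frac_sad: float = 0.0
    liability_slope: float = 0.0

    def __post_init__(self) -> None:
        for cat, row in self.research_confusion.items():
            if abs(sum(row) - 1.0) > 1e-9:
                raise ValueError(f"confusion row {cat} must sum to 1")


@dataclass
class CovariateEffects:
    """Group offsets between the reference-diagnosis group and the rest.

    Baselines approximate a clinically-ascertained sample; the reference
    (research-interview / medical-record) group is born ``yob_shift``
    years later (hence younger at interview) and differs on the logit
    scale for the binary phenotypes.  Zero offsets give exchangeable
    groups for null calibration.
    """

    interview_year: int = 2020
    yob_mean: float = 1973.0
    yob_sd: float = 13.0
    p_male: float = 0.63
    p_gcse: float = 0.73
    p_degree: float = 0.16
    p_employed: float = 0.30
    yob_shift: float = 4.0
    logit_male: float = 0.05
    logit_gcse: float = 0.48
    logit_degree: float = 0.14
    logit_employed: float = 0.3

    @classmethod
    def null(cls) -> "CovariateEffects":
        return cls(yob_shift=0.0, logit_male=0.0, logit_gcse=0.0, logit_degree=0.0, logit_employed=0.0)


@dataclass
class SimConfig:
    """Study-condition parameters for the synthetic cohort."""

    n_individuals: int = 2000
    # many small LD blocks: the pruned panel keeps >= ~400 near-independent
    # variants, enough that pairwise relatedness noise (sd ~ 1/sqrt(m))
    # stays well below the 0.1875 relatedness threshold
    n_variants: int = 2000
    block_size: int = 5
    within_block_r: float = 0.7
    freq_range: tuple[float, float] = (0.05, 0.5)
    n_causal: int = 200
    h2_prs: float = 0.05
    K_lifetime: float = 0.01
    n_train: int = 50_000
    pathway_params: PathwayParams = field(default_factory=PathwayParams)
    covariate_effects: CovariateEffects = field(default_factory=CovariateEffects)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.freq_range
        if not 0.0 < lo < hi < 1.0:
            raise ValueError(f"invalid freq_range {self.freq_range}")
        if not 0.0 <= self.h2_prs < 1.0:
            raise ValueError("h2_prs must lie in [0, 1)")
        if not 0.0 < self.K_lifetime < 1.0:
            raise ValueError("K_lifetime must lie in (0, 1)")
        if self.n_causal > self.n_variants:
            raise ValueError("n_causal cannot exceed n_variants")


@dataclass
class TrueState:
    """Generative ground truth for one simulated cohort."""

    liability: np.ndarray
    genetic: np.ndarray
    case: np.ndarray
    true_effect: np.ndarray  # per-variant effect on standardised dosages
    threshold: float


def _rng(cfg: SimConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, _STREAM[stage]])


# ---------------------------------------------------------------------------
# genotypes


def simulate_genotypes(cfg: SimConfig) -> GenotypeMatrix:
    """Biallelic dosages with compound-symmetry LD blocks.

    Each block shares one latent standard-normal factor per haplotype
    copy; each variant's haplotype allele is a Bernoulli-by-threshold draw
    from a latent correlated with the block factor at ``within_block_r``,
    so within-block dosage r^2 is about ``within_block_r`` squared and
    cross-block LD is null.
    """
    rng = _rng(cfg, "genotypes")
    n, m, bs = cfg.n_individuals, cfg.n_variants, cfg.block_size
    n_blocks = int(np.ceil(m / bs))
    freqs = rng.uniform(*cfg.freq_range, size=m)
    tau = norm.isf(freqs)  # latent > tau  <=>  allele carried, P = freq
    # loading sqrt(r) on the shared factor gives pairwise latent
    # correlation within_block_r between variants of a block
    load = np.sqrt(cfg.within_block_r)
    dosage = np.zeros((n, m), dtype=float)
    for hap in range(2):
        factors = rng.standard_normal((n, n_blocks))
        noise = rng.standard_normal((n, m))
        for b in range(n_blocks):
            j0, j1 = b * bs, min((b + 1) * bs, m)
            latent = load * factors[:, [b]] + np.sqrt(1 - cfg.within_block_r) * noise[:, j0:j1]
            dosage[:, j0:j1] += latent > tau[j0:j1]
    block_of = np.arange(m) // bs
    variants = pd.DataFrame(
        {
            "variant_id": [f"snp{j + 1}" for j in range(m)],
            "chromosome": (block_of % 22 + 1).astype(str),
            "position": (block_of // 22) * 1_000_000 + (np.arange(m) % bs) * 5_000 + 1,
            "allele_effect": "A",
            "allele_other": "G",
            "frequency_effect_allele": freqs,
        }
    )
    variants = variants.sort_values(["chromosome", "position"], kind="mergesort")
    order = variants.index.to_numpy()
    variants = variants.reset_index(drop=True)
    ids = [f"i{k + 1:05d}" for k in range(n)]
    return GenotypeMatrix(dosage[:, order], variants[VARIANT_COLUMNS], ids)


# ---------------------------------------------------------------------------
# phenotype


def simulate_phenotype(G: GenotypeMatrix, cfg: SimConfig) -> TrueState:
    """Liability-threshold case status from a sparse additive genetic score.

    ``n_causal`` variants get standard-normal effects on the standardised
    dosage scale, rescaled so the realised genetic component has variance
    ``h2_prs``; liability adds independent Gaussian noise of variance
    1 - ``h2_prs`` and cases exceed the upper-``K_lifetime`` quantile.
    """
    rng = _rng(cfg, "phenotype")
    n, m = G.dosages.shape
    b = np.zeros(m)
    g = np.zeros(n)
    if cfg.h2_prs > 0 and cfg.n_causal > 0:
        causal = rng.choice(m, size=cfg.n_causal, replace=False)
        raw = rng.standard_normal(cfg.n_causal)
        # clip guards monomorphic-in-sample variants at small n
        freq = np.clip(G.allele_frequencies(), 1e-3, 1 - 1e-3)
        Z = (np.nan_to_num(G.dosages) - 2 * freq) / np.sqrt(2 * freq * (1 - freq))
        g_raw = Z[:, causal] @ raw
        scale = np.sqrt(cfg.h2_prs) / g_raw.std()
        b[causal] = raw * scale
        g = g_raw * scale
    noise = rng.standard_normal(n) * np.sqrt(1.0 - cfg.h2_prs)
    liability = g + noise
    threshold = float(norm.isf(cfg.K_lifetime))
    return TrueState(liability, g, liability > threshold, b, threshold)


def simulate_liability_case_control(
    h2: float, K: float, n_case: int, n_control: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Case-control sample straight from the liability model (no genotypes).

    Returns (y, genetic score, liability) for an ascertained sample of
    ``n_case`` cases and ``n_control`` controls drawn from a population
    with liability-scale genetic variance ``h2`` and lifetime risk ``K``.
    """
    t = norm.isf(K)
    ys, gs, ls = [], [], []
    need_case, need_ctrl = n_case, n_control
    while need_case > 0 or need_ctrl > 0:
        chunk = max(int(1.5 * need_case / max(K, 1e-6)), 4 * need_ctrl, 10_000)
        g = rng.standard_normal(chunk) * np.sqrt(h2)
        liab = g + rng.standard_normal(chunk) * np.sqrt(1 - h2)
        case = liab > t
        ci = np.flatnonzero(case)[:need_case]
        ui = np.flatnonzero(~case)[:need_ctrl]
        take = np.concatenate([ci, ui])
        ys.append(case[take])
        gs.append(g[take])
        ls.append(liab[take])
        need_case -= ci.size
        need_ctrl -= ui.size
    y = np.concatenate(ys).astype(float)
    return y, np.concatenate(gs), np.concatenate(ls)


# ---------------------------------------------------------------------------
# summary statistics


def simulate_sumstats(state: TrueState, G: GenotypeMatrix, cfg: SimConfig) -> SummaryStats:
    """Training-GWAS effect estimates with sampling noise.

    True per-allele effects are the standardised-scale effects divided by
    the dosage SD sqrt(2f(1-f)); the sampling SE at training size
    ``n_train`` is 1/sqrt(2f(1-f) n_train) and the p-value is a two-sided
    Wald test.  Non-causal variants have true effect zero.
    """
    rng = _rng(cfg, "sumstats")
    v = G.variants
    f = v["frequency_effect_allele"].to_numpy(float)
    sd = np.sqrt(2 * f * (1 - f))
    beta_true = state.true_effect / sd
    se = 1.0 / (sd * np.sqrt(cfg.n_train))
    beta_hat = beta_true + rng.standard_normal(len(f)) * se
    p = 2.0 * norm.sf(np.abs(beta_hat / se))
    p = np.clip(p, 1e-300, 1.0)
    table = pd.DataFrame(
        {
            "variant_id": v["variant_id"],
            "chromosome": v["chromosome"],
            "position": v["position"],
            "allele_effect": v["allele_effect"],
            "allele_other": v["allele_other"],
            "effect_size": beta_hat,
            "se": se,
            "p": p,
            "frequency_effect_allele": f,
        }
    )
    return SummaryStats(table[SUMSTATS_COLUMNS])


# ---------------------------------------------------------------------------
# diagnosis pathways


def _coupled(p0: float, quantile: np.ndarray, slope: float) -> np.ndarray:
    """Monotone-in-liability probability: logit shift by slope*(q - 1/2)."""
    if slope == 0.0:
        return np.full_like(quantile, p0)
    return expit(logit(p0) + slope * (quantile - 0.5))


def simulate_pathways(state: TrueState, cfg: SimConfig) -> CohortTable:
    """Assign diagnosis records through three partially overlapping sources.

    Cases may acquire a medical-record diagnosis (admission count
    1 + Poisson, primary/secondary coding) and/or self-report (lifetime,
    with current/opinion subsets and 1 or 2+ endorsements); self-reporters
    proceed to a research interview whose category is drawn from the
    confusion row of the true category (clinically-ascertained design:
    non-self-reporters are never interviewed).  Controls self-report
    falsely at a small rate and are interview-negative; record-negative
    participants carry an explicit NONE medical-record row so NPV frames
    are well defined.
    """
    pp = cfg.pathway_params
    rng = _rng(cfg, "pathways")
    n = state.liability.size
    ids = np.array([f"i{k + 1:05d}" for k in range(n)])
    case = state.case
    # liability quantile among cases (0..1), drives severity coupling
    q = np.zeros(n)
    if case.any():
        ranks = state.liability[case].argsort().argsort()
        q[case] = (ranks + 0.5) / case.sum()
    true_cat = np.where(rng.random(n) < pp.frac_sad, "SA_D", "SZ")

    record = case & (rng.random(n) < _coupled(pp.p_record_given_case, q, pp.liability_slope))
    lam = pp.admission_lambda * np.where(
        pp.liability_slope > 0, np.exp(pp.liability_slope * (q - 0.5)), 1.0
    )
    admissions = 1 + rng.poisson(lam)
    primary = rng.random(n) < _coupled(pp.p_primary_admission, q, pp.liability_slope)

    p_sr = np.where(record, pp.p_selfreport_given_record, pp.p_selfreport_given_no_record)
    selfrep = case & (rng.random(n) < p_sr)
    selfrep |= (~case) & (rng.random(n) < pp.false_selfreport_rate)
    endorse2 = rng.random(n) < _coupled(pp.p_second_endorsement, q, pp.liability_slope)
    current = selfrep & (rng.random(n) < pp.p_current_given_lifetime)
    opinion = selfrep & (rng.random(n) < pp.p_opinion_given_lifetime)

    conf_rows = {k: np.asarray(v) for k, v in pp.research_confusion.items()}
    research_cat = np.full(n, "", dtype=object)
    for cat, row in conf_rows.items():
        mask = selfrep & case & (true_cat == cat)
        if mask.any():
            research_cat[mask] = rng.choice(CONFUSION_CATEGORIES, size=mask.sum(), p=row)
    research_cat[selfrep & ~case] = "NONE"

    rows = []
    for k in range(n):
        pid = ids[k]
        if record[k]:
            rows.append((pid, "medical_record", true_cat[k], int(admissions[k])))
            sub = "medical_record_primary" if primary[k] else "medical_record_secondary"
            rows.append((pid, sub, true_cat[k], int(admissions[k])))
        else:
            rows.append((pid, "medical_record", "NONE", 0))
        if selfrep[k]:
            cnt = 2 if endorse2[k] else 1
            rows.append((pid, "self_report_lifetime", "SZ", cnt))
            if current[k]:
                rows.append((pid, "self_report_current", "SZ", cnt))
            if opinion[k]:
                rows.append((pid, "self_report_opinion", "SZ", cnt))
            rows.append((pid, "research_interview", research_cat[k], 1))
    records = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    participants = pd.DataFrame({"participant_id": ids})
    for col in PARTICIPANT_COLUMNS[1:]:
        participants[col] = np.nan
    return CohortTable(participants, records)


def pathway_groups(cohort: CohortTable) -> dict[str, set[str]]:
    """Partition participants by diagnosis pathway.

    ``reference``: research-interview or medical-record SZ/SA-D diagnosis;
    ``self_report_only``: lifetime self-report without one; ``controls``:
    neither.
    """
    sz = {"SZ", "SA_D"}
    ref = (
        cohort.positives("research_interview", sz)
        | cohort.positives("medical_record", sz)
        | cohort.positives("medical_record_primary", sz)
        | cohort.positives("medical_record_secondary", sz)
    )
    sr = cohort.positives("self_report_lifetime", sz)
    everyone = set(cohort.participants["participant_id"])
    return {
        "reference": ref,
        "self_report_only": sr - ref,
        "controls": everyone - ref - sr,
    }


# ---------------------------------------------------------------------------
# covariates


def simulate_covariates(cohort: CohortTable, cfg: SimConfig) -> CohortTable:
    """Fill participant covariates with configured group offsets.

    The reference-diagnosis group is shifted relative to everyone else:
    born ``yob_shift`` years later and offset on the logit scale for sex,
    GCSE-or-above education, degree and employment.  Retirement tracks
    age (common past 65).
    """
    ce = cfg.covariate_effects
    rng = _rng(cfg, "covariates")
    groups = pathway_groups(cohort)
    p = cohort.participants.copy()
    n = len(p)
    in_ref = p["participant_id"].isin(groups["reference"]).to_numpy()
    yob = rng.normal(ce.yob_mean + ce.yob_shift * in_ref, ce.yob_sd).round().astype(int)
    age = np.maximum(ce.interview_year - yob, 18)

    def draw(p0: float, off: float) -> np.ndarray:
        prob = expit(logit(p0) + off * in_ref)
        return np.where(rng.random(n) < prob, "yes", "no")

    p["sex"] = np.where(rng.random(n) < expit(logit(ce.p_male) + ce.logit_male * in_ref), "male", "female")
    p["year_of_birth"] = yob
    p["age_at_interview"] = age
    p["education_gcse"] = draw(ce.p_gcse, ce.logit_gcse)
    p["degree"] = draw(ce.p_degree, ce.logit_degree)
    p["employed"] = draw(ce.p_employed, ce.logit_employed)
    p["retired"] = np.where((age >= 65) & (rng.random(n) < 0.8), "yes", "no")
    return CohortTable(p, cohort.records)


def simulate_cohort(cfg: SimConfig) -> tuple[GenotypeMatrix, TrueState, SummaryStats, CohortTable]:
    """Run the full generator: genotypes, phenotype, sumstats, cohort."""
    G = simulate_genotypes(cfg)
    state = simulate_phenotype(G, cfg)
    ss = simulate_sumstats(state, G, cfg)
    cohort = simulate_covariates(simulate_pathways(state, cfg), cfg)
    return G, state, ss, cohort
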