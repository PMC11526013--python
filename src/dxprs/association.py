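"""Group comparisons and variance-explained statistics.

Logistic regressions (statsmodels MLE) compare diagnosis-pathway groups
on phenotypes and on standardised polygenic scores; Nagelkerke pseudo-R^2
of a full-vs-covariates-only model pair is transformed to the liability
scale with the ascertainment correction for case-control sampling
(population lifetime risk K vs sample case fraction P); discrimination is
summarised by the Mann-Whitney AUC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm, rankdata

log = logging.getLogger(__name__)


@dataclass
class LiabilityParams:
    """Scales for the observed-to-liability conversion.

    K_lifetime: population lifetime risk (1% for schizophrenia);
    pi_point: population point prevalence (0.6%), used for predictive-value
    rescaling elsewhere, carried here for report plumbing.
    """

    K_lifetime: float = 0.01
    pi_point: float = 0.006

    def __post_init__(self) -> None:
        if not 0.0 < self.K_lifetime < 1.0 or not 0.0 < self.pi_point < 1.0:
            raise ValueError("prevalences must lie in (0, 1)")


@dataclass
class LogisticFit:
    params: np.ndarray
    cov: np.ndarray
    loglik: float
    loglik_null: float
    n: int
    names: list[str]

    def odds_ratio(self, term: str) -> tuple[float, float, float, float]:
        """(OR, ci_low, ci_high, p) for one coefficient (Wald, 95%)."""
        k = self.names.index(term)
        b = self.params[k]
        se = float(np.sqrt(self.cov[k, k]))
        zv = b / se
        p = 2.0 * norm.sf(abs(zv))
        return float(np.exp(b)), float(np.exp(b - 1.96 * se)), float(np.exp(b + 1.96 * se)), float(p)


@dataclass
class AssociationResult:
    """One fitted group comparison."""

    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    r2_obs: float | None = None
    r2_liab: float | None = None
    se_r2: float | None = None
    auc: float | None = None
    label: str = ""


class SeparationError(RuntimeError):
    pass


def fit_logistic(y, X, names: list[str] | None = None) -> LogisticFit:
    """Maximum-likelihood logistic fit with an added intercept.

    Raises :class:`SeparationError` naming the offending column on
    perfect separation or non-convergence.
    """
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != y.size:
        X = X.T
    if names is None:
        names = [f"x{k}" for k in range(X.shape[1])]
    if len(set(np.unique(y)) - {0.0, 1.0}) or np.unique(y).size < 2:
        raise ValueError("outcome must be binary with both classes present")
    Xc = sm.add_constant(X, has_constant="add")
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200, tol=1e-10)
    except Exception as exc:  # statsmodels raises PerfectSeparationError et al.
        raise SeparationError(f"logistic fit failed ({_blame_column(y, X, names)}): {exc}") from exc
    if not res.mle_retvals.get("converged", True):
        raise SeparationError(f"logistic fit did not converge ({_blame_column(y, X, names)})")
    return LogisticFit(
        params=np.asarray(res.params),
        cov=np.asarray(res.cov_params()),
        loglik=float(res.llf),
        loglik_null=float(res.llnull),
        n=int(y.size),
        names=["const"] + list(names),
    )


def _blame_column(y, X, names) -> str:
    for k in range(X.shape[1]):
        lo, hi = X[y == 0, k], X[y == 1, k]
        if lo.size and hi.size and (lo.max() < hi.min() or hi.max() < lo.min()):
            return f"column {names[k]!r} separates the classes"
    return "offending column not identified"


def nagelkerke_r2(fit: LogisticFit) -> float:
    """Nagelkerke pseudo-R^2 against the intercept-only model."""
    n = fit.n
    cs = 1.0 - np.exp(2.0 * (fit.loglik_null - fit.loglik) / n)
    denom = 1.0 - np.exp(2.0 * fit.loglik_null / n)
    return float(cs / denom)


def cox_snell_r2(fit: LogisticFit) -> float:
    return float(1.0 - np.exp(2.0 * (fit.loglik_null - fit.loglik) / fit.n))


def observed_to_liability(r2_obs: float, K: float, P: float) -> float:
    """Ascertainment-corrected observed-scale to liability-scale R^2.

    With t the upper-K normal quantile, z the normal density at t,
    m = z/K:  C = K(1-K)/z^2 * K(1-K)/(P(1-P)),
    theta = m ((P-K)/(1-K)) (m ((P-K)/(1-K)) - t),
    r2_liab = C r2 / (1 + C theta r2).
    """
    t = norm.isf(K)
    z = norm.pdf(t)
    m = z / K
    C = (K * (1 - K) / z**2) * (K * (1 - K) / (P * (1 - P)))
    d = m * (P - K) / (1 - K)
    theta = d * (d - t)
    return float(C * r2_obs / (1.0 + C * theta * r2_obs))


def variance_explained(
    y,
    X_base,
    prs_z,
    lp: LiabilityParams,
    pseudo_r2: str = "nagelkerke",
    n_boot: int = 200,
    seed: int = 0,
) -> tuple[float, float, float | None]:
    """Variance in case status explained by a PRS beyond base covariates.

    r2_obs is the pseudo-R^2 of (base + PRS) minus base; r2_liab applies
    the ascertainment-corrected liability transformation at
    K = ``lp.K_lifetime`` and P = sample case fraction.  The SE is a
    seeded individual-level bootstrap of r2_liab (skipped if
    ``n_boot`` == 0).
    """
    y = np.asarray(y, float)
    prs_z = np.asarray(prs_z, float)
    X_base = None if X_base is None else np.atleast_2d(np.asarray(X_base, float))
    if X_base is not None and X_base.shape[0] != y.size:
        X_base = X_base.T
    r2fun = nagelkerke_r2 if pseudo_r2 == "nagelkerke" else cox_snell_r2

    def delta_r2(idx) -> tuple[float, float]:
        # (reported flavour, Cox-Snell) increments; the liability
        # transformation is derived for the observed 0/1 scale, which
        # Cox-Snell approximates -- Nagelkerke's renormalisation would
        # inflate the converted value by ~1/(1 - exp(2 ll0 / n))
        yy = y[idx]
        pz = prs_z[idx]
        xb = None if X_base is None else X_base[idx]
        full = np.column_stack([xb, pz]) if xb is not None else pz[:, None]
        fit_full = fit_logistic(yy, full)
        r2_base = cs_base = 0.0
        if xb is not None:
            fit_base = fit_logistic(yy, xb)
            r2_base = r2fun(fit_base)
            cs_base = cox_snell_r2(fit_base)
        return r2fun(fit_full) - r2_base, cox_snell_r2(fit_full) - cs_base

    idx0 = np.arange(y.size)
    r2_obs, r2_cs = delta_r2(idx0)
    if r2_obs < 0 or r2_cs < 0:
        log.warning("negative incremental pseudo-R^2 (%.3g) clamped to 0", min(r2_obs, r2_cs))
        r2_obs, r2_cs = max(r2_obs, 0.0), max(r2_cs, 0.0)
    P = float(y.mean())
    r2_liab = observed_to_liability(r2_cs, lp.K_lifetime, P)
    se = None
    if n_boot:
        rng = np.random.default_rng(seed)
        boots = []
        for _ in range(n_boot):
            idx = rng.integers(0, y.size, y.size)
            if np.unique(y[idx]).size < 2:
                continue
            try:
                _, csb = delta_r2(idx)
            except (SeparationError, ValueError):
                continue
            boots.append(observed_to_liability(max(csb, 0.0), lp.K_lifetime, float(y[idx].mean())))
        se = float(np.std(boots, ddof=1)) if len(boots) > 1 else None
    return r2_obs, r2_liab, se


def auc(score, y) -> float:
    """Mann-Whitney AUC: P(case score > control score), ties half."""
    score = np.asarray(score, float)
    y = np.asarray(y, float)
    n1 = int(y.sum())
    n0 = int(y.size - n1)
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(score)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


# ---------------------------------------------------------------------------
# cohort-level comparisons

PHENOTYPES = ("sex", "age", "education_gcse", "degree", "employed")


def compare_phenotypes(
    cohort,
    group_a: set[str],
    group_b: set[str],
    age_per: str = "decade",
) -> dict[str, AssociationResult]:
    """Phenotype differences between two disjoint participant groups.

    Outcome: membership of ``group_b`` (vs ``group_a``).  Each phenotype
    is tested in a logistic regression with year of birth and sex as
    covariates (a covariate is dropped when it is itself the phenotype, or
    collinear with it, as year of birth is with age).  Employment is
    restricted to participants under 65 who did not report being retired.
    ``age_per`` scales age to decades (default) or years.
    """
    if group_a & group_b:
        raise ValueError("groups must be disjoint")
    if not group_a or not group_b:
        raise ValueError("groups must be non-empty")
    p = cohort.participants.set_index("participant_id")
    ids = [i for i in p.index if i in group_a or i in group_b]
    sub = p.loc[ids]
    yy = np.array([1.0 if i in group_b else 0.0 for i in ids])
    male = sub["sex"].map({"male": 1.0, "female": 0.0}).to_numpy(float)
    yob = sub["year_of_birth"].to_numpy(float)
    age = sub["age_at_interview"].to_numpy(float)
    if age_per == "decade":
        age = age / 10.0
    yesno = {"yes": 1.0, "no": 0.0}
    preds = {
        "sex": male,
        "age": age,
        "education_gcse": sub["education_gcse"].map(yesno).to_numpy(float),
        "degree": sub["degree"].map(yesno).to_numpy(float),
        "employed": sub["employed"].map(yesno).to_numpy(float),
    }
    results: dict[str, AssociationResult] = {}
    for pheno, x in preds.items():
        keep = np.isfinite(x) & np.isfinite(yy)
        covs = []
        names = [pheno]
        if pheno not in ("age",):  # age is collinear with year of birth
            covs.append(yob)
            names.append("year_of_birth")
        if pheno != "sex":
            covs.append(male)
            names.append("sex")
        for c in covs:
            keep &= np.isfinite(c)
        if pheno == "employed":
            age_yr = sub["age_at_interview"].to_numpy(float)
            retired = sub["retired"].map(yesno).to_numpy(float)
            keep &= (age_yr < 65) & (retired == 0.0)
        if keep.sum() == 0 or np.unique(yy[keep]).size < 2 or np.unique(x[keep]).size < 2:
            log.info("phenotype %s skipped: empty or constant subgroup", pheno)
            continue
        X = np.column_stack([x[keep]] + [c[keep] for c in covs])
        try:
            fit = fit_logistic(yy[keep], X, names)
        except SeparationError as exc:
            log.info("phenotype %s skipped: %s", pheno, exc)
            continue
        orr, lo, hi, pval = fit.odds_ratio(pheno)
        results[pheno] = AssociationResult(orr, lo, hi, pval, n=int(keep.sum()), label=pheno)
    return results


def severity_gradient(
    prs_z,
    groups,
    covariates=None,
    control_label: str = "controls",
) -> dict[str, AssociationResult]:
    """PRS severity gradient across ordinal diagnosis-intensity levels.

    Each non-control level is compared with controls in a logistic fit of
    level membership on the standardised PRS (plus covariates); adjacent
    non-control levels are contrasted within cases only.  Empty levels are
    dropped with a warning.
    """
    prs_z = np.asarray(prs_z, float)
    groups = np.asarray(groups, object)
    covariates = None if covariates is None else np.atleast_2d(np.asarray(covariates, float))
    if covariates is not None and covariates.shape[0] != prs_z.size:
        covariates = covariates.T
    levels = [g for g in pd.unique(groups) if g != control_label]
    results: dict[str, AssociationResult] = {}

    def _fit(mask_case, mask_ref, label):
        mask = mask_case | mask_ref
        yy = mask_case[mask].astype(float)
        X = prs_z[mask][:, None]
        names = ["prs_z"]
        if covariates is not None:
            X = np.column_stack([X, covariates[mask]])
            names += [f"cov{k}" for k in range(covariates.shape[1])]
        fit = fit_logistic(yy, X, names)
        orr, lo, hi, pval = fit.odds_ratio("prs_z")
        results[label] = AssociationResult(orr, lo, hi, pval, n=int(mask.sum()), label=label)

    ctrl = groups == control_label
    for lev in levels:
        mask = groups == lev
        if not mask.any():
            log.warning("severity level %r empty: dropped", lev)
            continue
        _fit(mask, ctrl, f"{lev}_vs_{control_label}")
    for a, b in zip(levels, levels[1:]):
        ma, mb = groups == a, groups == b
        if ma.any() and mb.any():
            _fit(mb, ma, f"{b}_vs_{a}")
    return results
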