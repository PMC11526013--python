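"""Variant- and individual-level genotype quality control.

Variant filters: minor-allele frequency, call rate, and an exact
Hardy-Weinberg test.  Individual filters: relatedness (on the
IBD-proportion scale, where duplicates sit near 1 and first-degree
relatives near 0.5) and PCA-based ancestry clustering that keeps the
most central fraction of the sample.  LD pruning walks a sliding window
of fixed variant count and greedily drops the lower-MAF member of any
pair whose dosage r^2 exceeds the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .datatypes import GenotypeMatrix


@dataclass
class QCThresholds:
    """Thresholds for the QC pipeline (defaults: common GWAS practice)."""

    maf_min: float = 0.05
    missing_max: float = 0.05
    hwe_p_max: float = 1e-6          # removal at p <= hwe_p_max (inclusive)
    prune_window: int = 500          # variants per LD-pruning window
    prune_step: int = 20             # variants to shift the window
    prune_r2: float = 0.2
    dup_coeff: float = 0.98          # IBD-proportion above which a pair is duplicate
    rel_coeff: float = 0.1875        # ... above which a pair is related
    n_pcs: int = 5
    keep_frac: float = 0.90          # fraction of most-central individuals kept
    hwe_method: str = "exact"        # or "chisq"

    def __post_init__(self) -> None:
        for name in ("maf_min", "missing_max", "prune_r2", "keep_frac"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if not self.prune_window > self.prune_step > 0:
            raise ValueError("need prune_window > prune_step > 0")


# ---------------------------------------------------------------------------
# Hardy-Weinberg


def hwe_test(n_AA: int, n_Aa: int, n_aa: int, method: str = "exact") -> float:
    """Hardy-Weinberg equilibrium test p-value from genotype counts.

    The exact conditional test sums, over all heterozygote counts
    compatible with the observed allele counts, the probabilities of
    tables no more likely than the observed one.  Monomorphic variants
    have a single possible table and return 1.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("no genotyped individuals")
    if method == "chisq":
        return _hwe_chisq(n_AA, n_Aa, n_aa)
    n_a = 2 * n_aa + n_Aa  # minor-ish allele count (either works; symmetric)
    if n_a == 0 or n_a == 2 * n:
        return 1.0
    hets = np.arange(n_a % 2, min(n_a, 2 * n - n_a) + 1, 2)
    # log P(het = h | allele counts) up to a shared constant
    logp = (
        hets * np.log(2.0)
        - gammaln(hets + 1)
        - gammaln((n_a - hets) // 2 + 1)
        - gammaln((2 * n - n_a - hets) // 2 + 1)
    )
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    p_obs = p[np.flatnonzero(hets == n_Aa)[0]]
    return float(min(1.0, p[p <= p_obs * (1 + 1e-12)].sum()))


def _hwe_chisq(n_AA: int, n_Aa: int, n_aa: int) -> float:
    from scipy.stats import chi2

    n = n_AA + n_Aa + n_aa
    p = (2 * n_AA + n_Aa) / (2 * n)
    q = 1 - p
    if p == 0 or q == 0:
        return 1.0
    exp = np.array([n * p * p, 2 * n * p * q, n * q * q])
    obs = np.array([n_AA, n_Aa, n_aa])
    stat = ((obs - exp) ** 2 / exp).sum()
    return float(chi2.sf(stat, df=1))


# ---------------------------------------------------------------------------
# variant filters


def snp_qc(G: GenotypeMatrix, thr: QCThresholds) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Apply MAF / missingness / HWE filters.

    Returns the retained matrix and a per-removed-variant table tagging
    every reason that applied.  HWE is computed on hard calls (dosages
    rounded to the nearest genotype).
    """
    if G.n_variants == 0:
        raise ValueError("empty genotype matrix")
    freq = G.allele_frequencies()
    maf = np.minimum(freq, 1 - freq)
    miss = G.missingness()
    hwe_p = np.ones(G.n_variants)
    hard = np.round(G.dosages)
    for j in range(G.n_variants):
        col = hard[:, j]
        ok = ~np.isnan(col)
        if not ok.any():
            continue
        n_aa = int((col[ok] == 0).sum())
        n_Aa = int((col[ok] == 1).sum())
        n_AA = int((col[ok] == 2).sum())
        hwe_p[j] = hwe_test(n_AA, n_Aa, n_aa, method=thr.hwe_method)
    fail_maf = ~(maf >= thr.maf_min)  # NaN frequency (all-missing) also fails
    fail_miss = miss > thr.missing_max
    fail_hwe = hwe_p <= thr.hwe_p_max
    removed = fail_maf | fail_miss | fail_hwe
    reasons = []
    for j in np.flatnonzero(removed):
        tags = []
        if fail_maf[j]:
            tags.append("maf")
        if fail_miss[j]:
            tags.append("missingness")
        if fail_hwe[j]:
            tags.append("hwe")
        reasons.append(
            {
                "variant_id": G.variants["variant_id"].iloc[j],
                "reasons": ";".join(tags),
                "maf": maf[j],
                "missingness": miss[j],
                "hwe_p": hwe_p[j],
            }
        )
    kept = G.subset_variants(np.flatnonzero(~removed))
    return kept, pd.DataFrame(reasons, columns=["variant_id", "reasons", "maf", "missingness", "hwe_p"])


# ---------------------------------------------------------------------------
# LD


def ld_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors over complete pairs."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 2:
        raise ValueError("need >= 2 complete pairwise observations")
    xs, ys = x[ok], y[ok]
    vx, vy = xs.var(), ys.var()
    if vx == 0 or vy == 0:
        return 0.0  # undefined correlation: treated as no LD for pruning
    c = np.cov(xs, ys)[0, 1]
    return float(c * c / (xs.var(ddof=1) * ys.var(ddof=1)))


def _imputed_standardised(dosages: np.ndarray) -> np.ndarray:
    """Mean-impute missing dosages, then centre/scale each variant column."""
    X = np.array(dosages, float)
    mean = np.nanmean(X, axis=0)
    nan_cols = np.isnan(mean)
    mean[nan_cols] = 0.0
    idx = np.where(np.isnan(X))
    X[idx] = mean[idx[1]]
    X -= mean
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return X / sd


def _window_r2(Xs: np.ndarray) -> np.ndarray:
    n = Xs.shape[0]
    r = (Xs.T @ Xs) / n
    return r * r


def ld_prune(G: GenotypeMatrix, thr: QCThresholds) -> np.ndarray:
    """Windowed greedy LD pruning; returns kept variant indices.

    Variants must be sorted by (chromosome, position).  Windows of
    ``prune_window`` variants advance by ``prune_step`` within each
    chromosome; inside a window, while any kept pair exceeds ``prune_r2``
    the lower-MAF member is dropped (ties drop the later position).
    """
    chrom = G.variants["chromosome"].to_numpy()
    pos = G.variants["position"].to_numpy()
    order = np.lexsort((pos, chrom))
    if not np.array_equal(order, np.arange(len(order))):
        raise ValueError("variants must be sorted by (chromosome, position) before pruning")
    freq = G.allele_frequencies()
    maf = np.minimum(freq, 1 - freq)
    Xs = _imputed_standardised(G.dosages)
    keep = np.ones(G.n_variants, bool)
    for chrom_val in pd.unique(pd.Series(chrom)):
        idx = np.flatnonzero(chrom == chrom_val)
        start = 0
        while True:
            window = idx[start : start + thr.prune_window]
            if len(window) > 1:
                _prune_window(window, Xs, maf, keep, thr.prune_r2)
            if start + thr.prune_window >= len(idx):
                break
            start += thr.prune_step
    return np.flatnonzero(keep)


def _prune_window(window: np.ndarray, Xs: np.ndarray, maf: np.ndarray, keep: np.ndarray, r2_max: float) -> None:
    active = [j for j in window if keep[j]]
    if len(active) < 2:
        return
    r2 = _window_r2(Xs[:, active])
    alive = np.ones(len(active), bool)
    while True:
        offender = None
        for a in range(len(active)):
            if not alive[a]:
                continue
            for b in range(a + 1, len(active)):
                if alive[b] and r2[a, b] > r2_max:
                    offender = (a, b)
                    break
            if offender:
                break
        if offender is None:
            break
        a, b = offender
        ja, jb = active[a], active[b]
        # drop lower MAF; tie -> later position (b is later: window is sorted)
        drop = b if (maf[jb] < maf[ja] or maf[ja] == maf[jb]) else a
        alive[drop] = False
        keep[active[drop]] = False


# ---------------------------------------------------------------------------
# relatedness


def relatedness_matrix(G_pruned: GenotypeMatrix) -> np.ndarray:
    """Genome-wide relatedness on the IBD-proportion scale.

    Standardised-dosage correlation across variants: duplicates ~1,
    parent-offspring/full sibs ~0.5, unrelated ~0.  Diagonal fixed at 1.
    """
    if G_pruned.n_individuals < 2:
        raise ValueError("need >= 2 individuals")
    Xs = _imputed_standardised(G_pruned.dosages)
    # correlation form: normalising each individual's standardised-dosage
    # vector removes the small-sample shrinkage of the plain Z Z'/m GRM,
    # so duplicate rows score exactly 1 at any sample size
    norms = np.linalg.norm(Xs, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    Zn = Xs / norms
    A = Zn @ Zn.T
    np.fill_diagonal(A, 1.0)
    return A


def relatedness_filter(
    coeffs: np.ndarray, thr: QCThresholds, seed: int
) -> tuple[np.ndarray, pd.DataFrame]:
    """Remove one member (seeded uniform draw) of each over-threshold pair.

    Returns kept indices and a removal log (pair, coefficient, removed).
    """
    A = np.asarray(coeffs, float)
    n = A.shape[0]
    rng = np.random.default_rng(seed)
    alive = np.ones(n, bool)
    log = []
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n) if A[i, j] > thr.rel_coeff]
    for i, j in pairs:
        if alive[i] and alive[j]:
            drop = int(rng.choice([i, j]))
            alive[drop] = False
            log.append({"i": i, "j": j, "coefficient": A[i, j], "removed": drop})
    return np.flatnonzero(alive), pd.DataFrame(log, columns=["i", "j", "coefficient", "removed"])


# ---------------------------------------------------------------------------
# PCA ancestry clustering


@dataclass
class PCAResult:
    scores: np.ndarray                    # individuals x n_pcs
    kept: np.ndarray = field(default=None)  # indices of retained individuals
    distances: np.ndarray = field(default=None)


def pca_cluster(G_pruned: GenotypeMatrix, thr: QCThresholds) -> PCAResult:
    """PCA on standardised dosages + central-distance ancestry clustering.

    Keeps the ``keep_frac`` proportion of individuals (ceiling) closest in
    Euclidean distance to the centroid of the first ``n_pcs`` principal
    component scores.
    """
    n = G_pruned.n_individuals
    if n < thr.n_pcs + 1:
        raise ValueError(f"need at least {thr.n_pcs + 1} individuals for {thr.n_pcs} PCs")
    Xs = _imputed_standardised(G_pruned.dosages)
    if not Xs.any():
        raise np.linalg.LinAlgError("constant genotype matrix: no principal components")
    U, S, _ = np.linalg.svd(Xs, full_matrices=False)
    k = min(thr.n_pcs, S.size)
    scores = U[:, :k] * S[:k]
    centroid = scores.mean(axis=0)
    dist = np.linalg.norm(scores - centroid, axis=1)
    n_keep = int(np.ceil(thr.keep_frac * n))
    kept = np.sort(np.argsort(dist, kind="stable")[:n_keep])
    return PCAResult(scores=scores, kept=kept, distances=dist)
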