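"""Clumping-and-thresholding polygenic scores.

Summary statistics are filtered to common variants (MAF > 0.01) outside
the extended MHC, greedily clumped to relatively independent index SNPs
(r^2 < clump threshold within a kb window, most significant first), and
variants passing the p-value threshold are summed as dosage-weighted
log-odds.  Scores are standardised within the scored sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix, SummaryStats
from .qc import _imputed_standardised

log = logging.getLogger(__name__)

PALINDROMIC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass
class PRSConfig:
    """Clumping + thresholding parameters.

    The MHC exclusion is chr6:25-34 Mb (GRCh37, inclusive bounds), the
    conventional extended-MHC window for schizophrenia scores.
    """

    clump_r2: float = 0.1
    clump_window_kb: float = 500.0
    p_threshold: float = 0.05
    maf_min: float = 0.01
    mhc_region: tuple[str, int, int] = ("6", 25_000_000, 34_000_000)

    def __post_init__(self) -> None:
        if not 0.0 < self.clump_r2 < 1.0 or not 0.0 < self.p_threshold <= 1.0:
            raise ValueError("thresholds must lie in (0, 1)")
        if self.clump_window_kb <= 0:
            raise ValueError("clump window must be positive")


@dataclass
class PRSVector:
    """Per-individual raw and within-sample standardised scores."""

    individual_ids: list[str]
    raw: np.ndarray
    z: np.ndarray
    n_variants: int = 0
    skipped: list[str] = field(default_factory=list)


class EmptyPanelError(ValueError):
    pass


def filter_sumstats(ss: SummaryStats, cfg: PRSConfig, frequencies: np.ndarray | None = None) -> SummaryStats:
    """Keep variants with MAF strictly above ``maf_min`` outside the MHC.

    ``frequencies`` (effect-allele, aligned with ``ss``) overrides the
    frequency column, e.g. when only the target sample has them.
    """
    t = ss.table
    freq = np.asarray(frequencies, float) if frequencies is not None else t["frequency_effect_allele"].to_numpy(float)
    if np.isnan(freq).all():
        raise ValueError("allele frequencies unavailable: cannot apply the MAF filter")
    maf = np.minimum(freq, 1 - freq)
    chrom, lo, hi = cfg.mhc_region
    in_mhc = (t["chromosome"].astype(str) == str(chrom)) & t["position"].between(lo, hi)
    keep = (maf > cfg.maf_min) & ~in_mhc.to_numpy()
    if not keep.any():
        raise EmptyPanelError("no variants survive the MAF/MHC filter")
    return SummaryStats(t.loc[keep].reset_index(drop=True))


def clump(ss: SummaryStats, G_ref: GenotypeMatrix, cfg: PRSConfig) -> tuple[SummaryStats, list[str]]:
    """Greedy LD clumping against reference genotypes.

    Variants are visited by ascending p (ties by chromosome, position);
    each unclaimed visit becomes an index SNP and claims every unclaimed
    variant within ``clump_window_kb`` whose r^2 with it reaches
    ``clump_r2``.  Variants absent from the reference are skipped (logged,
    not fatal).  Returns (index-SNP summary stats, skipped variant ids).
    """
    t = ss.table
    ref_col = {vid: j for j, vid in enumerate(G_ref.variants["variant_id"])}
    present = t["variant_id"].map(ref_col)
    skipped = list(t.loc[present.isna(), "variant_id"])
    if skipped:
        log.info("clump: %d variants absent from reference genotypes", len(skipped))
    t = t.loc[present.notna()].reset_index(drop=True)
    cols = present.dropna().astype(int).to_numpy()
    order = np.lexsort((t["position"], t["chromosome"], t["p"]))
    Xs = _imputed_standardised(G_ref.dosages)
    n = Xs.shape[0]
    claimed = np.zeros(len(t), bool)
    index_rows = []
    window = cfg.clump_window_kb * 1000.0
    chroms = t["chromosome"].to_numpy()
    positions = t["position"].to_numpy(float)
    for i in order:
        if claimed[i]:
            continue
        claimed[i] = True
        index_rows.append(i)
        near = np.flatnonzero(
            (~claimed) & (chroms == chroms[i]) & (np.abs(positions - positions[i]) <= window)
        )
        if near.size:
            r = (Xs[:, cols[near]].T @ Xs[:, cols[i]]) / n
            claimed[near[r * r >= cfg.clump_r2]] = True
    index_rows = sorted(index_rows)
    return SummaryStats(t.iloc[index_rows].reset_index(drop=True)), skipped


def reconcile_alleles(
    ss_effect: str, ss_other: str, g_effect: str, g_other: str
) -> int | None:
    """Match summary-stat alleles to genotype alleles.

    Returns +1 for an exact match, -1 for a swapped match (effect size
    must be negated), None when the alleles are irreconcilable.  No
    strand flipping is attempted; ambiguous palindromic pairs are the
    caller's concern when frequencies are unavailable.
    """
    if (ss_effect, ss_other) == (g_effect, g_other):
        return 1
    if (ss_effect, ss_other) == (g_other, g_effect):
        return -1
    return None


def score(G: GenotypeMatrix, ss_clumped: SummaryStats, cfg: PRSConfig) -> PRSVector:
    """Dosage-weighted sum of clumped effects passing the p threshold.

    Missing dosages are imputed as twice the effect-allele frequency
    (target-sample estimate).  Palindromic variants are rejected when no
    frequency is available to orient them; swapped-allele variants
    contribute with negated effect.  Scores are z-standardised within the
    scored sample.
    """
    t = ss_clumped.table
    t = t.loc[t["p"] <= cfg.p_threshold]
    gmeta = G.variants.set_index("variant_id")
    freqs = G.allele_frequencies()
    col_of = {vid: j for j, vid in enumerate(G.variants["variant_id"])}
    raw = np.zeros(G.n_individuals)
    used = 0
    skipped: list[str] = []
    for _, row in t.iterrows():
        vid = row["variant_id"]
        if vid not in col_of:
            skipped.append(vid)
            continue
        j = col_of[vid]
        g = gmeta.loc[vid]
        sign = reconcile_alleles(
            row["allele_effect"], row["allele_other"], g["allele_effect"], g["allele_other"]
        )
        if sign is None:
            skipped.append(vid)
            continue
        pair = (str(row["allele_effect"]).upper(), str(row["allele_other"]).upper())
        if pair in PALINDROMIC and np.isnan(row["frequency_effect_allele"]):
            skipped.append(vid)
            continue
        dos = G.dosages[:, j]
        fill = 2.0 * freqs[j] if np.isfinite(freqs[j]) else 1.0
        dos = np.where(np.isnan(dos), fill, dos)
        raw += dos * (sign * row["effect_size"])
        used += 1
    if used == 0:
        raise EmptyPanelError("no variants scored after thresholding and allele reconciliation")
    sd = raw.std()
    z = (raw - raw.mean()) / sd if sd > 0 else np.zeros_like(raw)
    return PRSVector(list(G.individual_ids), raw, z, n_variants=used, skipped=skipped)
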