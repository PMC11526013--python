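"""Core in-memory containers shared across the pipeline.

Genotypes live in a dense individuals x variants dosage matrix (NaN =
missing call); variant metadata and summary statistics are pandas
DataFrames; the cohort is a pair of DataFrames (one participant row each,
one row per diagnosis record).  Coordinates are 1-based inclusive
throughout, following VCF convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Closed vocabulary of diagnosis sources.  The two medical-record
#: refinements distinguish admissions where the psychosis code was the
#: reason for admission (primary) from coexisting-condition codes.
DIAGNOSIS_SOURCES = (
    "self_report_lifetime",
    "self_report_current",
    "self_report_opinion",
    "research_interview",
    "medical_record",
    "medical_record_primary",
    "medical_record_secondary",
)

#: Closed vocabulary of diagnosis categories.  OTHER_PSYCHOTIC covers
#: non-schizophrenia psychotic disorders (psychosis NOS, schizophreniform,
#: delusional, brief psychotic, acute polymorphic and related illnesses);
#: SA_D is schizoaffective disorder, depressed type.
DIAGNOSIS_CATEGORIES = ("SZ", "SA_D", "OTHER_PSYCHOTIC", "MOOD", "OTHER", "NONE")

VARIANT_COLUMNS = [
    "variant_id",
    "chromosome",
    "position",
    "allele_effect",
    "allele_other",
    "frequency_effect_allele",
]

SUMSTATS_COLUMNS = VARIANT_COLUMNS[:5] + ["effect_size", "se", "p", "frequency_effect_allele"]

PARTICIPANT_COLUMNS = [
    "participant_id",
    "sex",
    "year_of_birth",
    "age_at_interview",
    "education_gcse",
    "degree",
    "employed",
    "retired",
]

RECORD_COLUMNS = ["participant_id", "source", "category", "count"]


class DxprsError(Exception):
    """Base class for pipeline errors."""


class SchemaError(DxprsError):
    """A file is missing required columns or carries duplicate keys."""


class VocabularyError(DxprsError):
    """A token falls outside a closed vocabulary."""


class DegenerateTableError(DxprsError):
    """A contingency table has no information for the requested rate."""


def validate_variant_table(variants: pd.DataFrame) -> pd.DataFrame:
    """Check variant metadata invariants and return a normalised copy."""
    missing = [c for c in VARIANT_COLUMNS[:5] if c not in variants.columns]
    if missing:
        raise SchemaError(f"variant table missing columns: {missing}")
    v = variants.copy()
    if "frequency_effect_allele" not in v.columns:
        v["frequency_effect_allele"] = np.nan
    v["chromosome"] = v["chromosome"].astype(str)
    v["position"] = v["position"].astype(np.int64)
    if (v["position"] <= 0).any():
        bad = v.loc[v["position"] <= 0, "variant_id"].iloc[0]
        raise SchemaError(f"non-positive position for variant {bad!r}")
    dup = v["variant_id"][v["variant_id"].duplicated()]
    if len(dup):
        raise SchemaError(f"duplicated variant ids: {sorted(set(dup))}")
    empty = (v["allele_effect"].astype(str) == "") | (v["allele_other"].astype(str) == "")
    same = v["allele_effect"].astype(str) == v["allele_other"].astype(str)
    if (empty | same).any():
        bad = v.loc[empty | same, "variant_id"].iloc[0]
        raise SchemaError(f"invalid alleles for variant {bad!r}")
    return v.reset_index(drop=True)


@dataclass
class GenotypeMatrix:
    """Individuals x biallelic-variants dosage matrix with metadata.

    ``dosages[i, j]`` is the expected count of the effect (ALT) allele of
    variant ``j`` carried by individual ``i``, in [0, 2]; missing calls are
    NaN.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    individual_ids: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-dimensional")
        self.variants = validate_variant_table(self.variants)
        self.individual_ids = [str(i) for i in self.individual_ids]
        n, m = self.dosages.shape
        if len(self.individual_ids) != n or len(self.variants) != m:
            raise ValueError(
                f"dimension mismatch: dosages {self.dosages.shape}, "
                f"{len(self.individual_ids)} individuals, {len(self.variants)} variants"
            )
        if len(set(self.individual_ids)) != n:
            raise SchemaError("duplicate individual ids")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.dosages, initial=0.0) < 0 or np.nanmax(self.dosages, initial=0.0) > 2:
                raise ValueError("dosages must lie in [0, 2]")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def allele_frequencies(self) -> np.ndarray:
        """Per-variant effect-allele frequency from non-missing dosages."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def missingness(self) -> np.ndarray:
        """Per-variant fraction of missing calls."""
        return np.isnan(self.dosages).mean(axis=0)

    def subset_variants(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            self.dosages[:, index],
            self.variants.iloc[index].reset_index(drop=True),
            list(self.individual_ids),
        )

    def subset_individuals(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            self.dosages[index, :],
            self.variants.copy(),
            [self.individual_ids[i] for i in index],
        )


@dataclass
class SummaryStats:
    """Per-variant training-GWAS effect estimates (log-odds scale)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SUMSTATS_COLUMNS if c not in self.table.columns]
        if missing:
            raise SchemaError(f"summary statistics missing columns: {missing}")
        t = self.table.copy()
        t["chromosome"] = t["chromosome"].astype(str)
        t["position"] = t["position"].astype(np.int64)
        dup = t["variant_id"][t["variant_id"].duplicated()]
        if len(dup):
            raise SchemaError(f"duplicated variant ids in summary statistics: {sorted(set(dup))}")
        p = t["p"].to_numpy(float)
        bad = np.flatnonzero(~((p > 0) & (p <= 1)))
        if bad.size:
            raise ValueError(f"p-value out of (0, 1] at row {bad[0]}")
        if not np.isfinite(t["effect_size"].to_numpy(float)).all():
            raise ValueError("non-finite effect size in summary statistics")
        self.table = t.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def sorted_by_position(self) -> "SummaryStats":
        return SummaryStats(
            self.table.sort_values(["chromosome", "position"], kind="mergesort").reset_index(drop=True)
        )


@dataclass
class CohortTable:
    """Participants plus their source-tagged diagnosis records.

    ``participants`` has one row per participant (covariates; categorical
    fields use the strings yes/no/male/female, NaN for missing).
    ``records`` has one row per (participant, source, category) with a
    non-negative ``count`` (endorsement or admission count).
    """

    participants: pd.DataFrame
    records: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=RECORD_COLUMNS))

    def __post_init__(self) -> None:
        missing = [c for c in PARTICIPANT_COLUMNS if c not in self.participants.columns]
        if missing:
            raise SchemaError(f"cohort table missing columns: {missing}")
        p = self.participants.copy()
        p["participant_id"] = p["participant_id"].astype(str)
        dup = p["participant_id"][p["participant_id"].duplicated()]
        if len(dup):
            raise SchemaError(f"duplicated participant ids: {sorted(set(dup))}")
        r = self.records.copy()
        for c in RECORD_COLUMNS:
            if c not in r.columns:
                raise SchemaError(f"record table missing column {c!r}")
        if len(r):
            r["participant_id"] = r["participant_id"].astype(str)
            bad_src = set(r["source"]) - set(DIAGNOSIS_SOURCES)
            if bad_src:
                raise VocabularyError(f"unknown diagnosis source tokens: {sorted(bad_src)}")
            bad_cat = set(r["category"]) - set(DIAGNOSIS_CATEGORIES)
            if bad_cat:
                raise VocabularyError(f"unknown diagnosis category tokens: {sorted(bad_cat)}")
            if (r["count"].to_numpy(float) < 0).any():
                raise ValueError("negative record count")
        self.participants = p.reset_index(drop=True)
        self.records = r.reset_index(drop=True)

    @property
    def n_participants(self) -> int:
        return len(self.participants)

    def positives(self, source: str, categories) -> set[str]:
        """Participant ids with >=1 record of ``source`` in ``categories``."""
        if source not in DIAGNOSIS_SOURCES:
            raise VocabularyError(f"unknown diagnosis source {source!r}")
        categories = set(categories)
        r = self.records
        mask = (r["source"] == source) & r["category"].isin(categories)
        return set(r.loc[mask, "participant_id"])

    def assessed(self, source: str) -> set[str]:
        """Participant ids carrying any record of ``source`` (NONE included)."""
        if source not in DIAGNOSIS_SOURCES:
            raise VocabularyError(f"unknown diagnosis source {source!r}")
        return set(self.records.loc[self.records["source"] == source, "participant_id"])
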