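"""Diagnostic concordance between self-report, interview and record sources.

Cross-tabulates an index diagnosis source against a reference source and
computes predictive values.  In a clinically-ascertained design (only
index-positive participants were assessed by the reference) sensitivity,
specificity and NPV are undefined and are reported as missing rather than
computed from the biased sampling frame; PPV remains valid.  PPV/NPV from
a population-representative table can be restated at an external point
prevalence pi via Bayes' rule on sensitivity and specificity.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import pandas as pd

from .datatypes import CohortTable, DegenerateTableError, VocabularyError

_ICD10 = re.compile(r"^([A-Z])(\d{2})(?:\.(\d+))?$")

#: Reference-category ladder used in the self-report PPV report: the
#: reference set widens from schizophrenia alone, to schizophrenia or
#: schizoaffective-depressed, to any psychotic disorder.
CATEGORY_LADDER = (
    ("SZ", frozenset({"SZ"})),
    ("SZ/SA-D", frozenset({"SZ", "SA_D"})),
    ("SZ/SA-D/other psychotic", frozenset({"SZ", "SA_D", "OTHER_PSYCHOTIC"})),
)

SELF_REPORT_SUBTYPES = (
    "self_report_lifetime",
    "self_report_current",
    "self_report_opinion",
)


def map_icd10(codes: list[str]) -> set[str]:
    """Map ICD-10 codes to diagnosis categories.

    F20.* is schizophrenia; F25.1 schizoaffective depressed type; the rest
    of F21-F29 other psychotic disorders; F30-F39 mood disorders; any
    other valid code OTHER.  An empty list maps to {NONE}.
    """
    if not codes:
        return {"NONE"}
    out: set[str] = set()
    for code in codes:
        m = _ICD10.match(str(code).strip().upper())
        if not m:
            raise VocabularyError(f"token {code!r} is not an ICD-10-shaped code")
        letter, major, minor = m.group(1), int(m.group(2)), m.group(3)
        if letter != "F":
            out.add("OTHER")
        elif major == 20:
            out.add("SZ")
        elif major == 25 and minor is not None and minor.startswith("1"):
            out.add("SA_D")
        elif 21 <= major <= 29:
            out.add("OTHER_PSYCHOTIC")
        elif 30 <= major <= 39:
            out.add("MOOD")
        else:
            out.add("OTHER")
    return out


@dataclass
class ContingencyTable:
    """2x2 cross-tabulation of index vs reference diagnosis.

    ``fn``/``tn`` are None for clinically-ascertained (index-restricted)
    designs where index-negatives were never sampled.
    """

    tp: int
    fp: int
    fn: int | None = None
    tn: int | None = None
    n_excluded: int = 0

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")
        cells = [c for c in (self.tp, self.fp, self.fn, self.tn) if c is not None]
        if sum(cells) == 0:
            raise DegenerateTableError("contingency table has no observations")


@dataclass
class PredictiveValues:
    """PPV/NPV/sensitivity/specificity, optionally restated at prevalence pi."""

    ppv: float
    npv: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    ppv_adjusted: float | None = None
    npv_adjusted: float | None = None
    prevalence_pi: float | None = None


def build_contingency(
    cohort: CohortTable,
    index_source: str,
    index_set,
    reference_source: str,
    reference_set,
    restrict_to_index_positive: bool = False,
) -> ContingencyTable:
    """Cross-tabulate index-source against reference-source diagnoses.

    A participant is index-positive if ANY record of the index source falls
    in ``index_set`` (participants could endorse several diagnoses), and is
    reference-assessed if they carry any record of the reference source
    (category NONE encodes assessed-but-negative).  Unassessed participants
    are excluded and tallied in ``n_excluded``.
    """
    if cohort.n_participants == 0:
        raise DegenerateTableError("empty cohort")
    idx_pos = cohort.positives(index_source, index_set)
    assessed = cohort.assessed(reference_source)
    # refinement sources count as assessment by the parent record source
    if reference_source == "medical_record":
        assessed |= cohort.assessed("medical_record_primary")
        assessed |= cohort.assessed("medical_record_secondary")
    ref_pos = cohort.positives(reference_source, reference_set)
    if reference_source == "medical_record":
        ref_pos |= cohort.positives("medical_record_primary", reference_set)
        ref_pos |= cohort.positives("medical_record_secondary", reference_set)

    everyone = set(cohort.participants["participant_id"])
    frame = (idx_pos & everyone) if restrict_to_index_positive else everyone
    in_frame_assessed = frame & assessed
    n_excluded = len(frame - assessed)
    if not in_frame_assessed:
        raise DegenerateTableError(
            "no participants assessed by the reference source in the tabulation frame"
        )
    tp = len(in_frame_assessed & idx_pos & ref_pos)
    fp = len((in_frame_assessed & idx_pos) - ref_pos)
    if restrict_to_index_positive:
        return ContingencyTable(tp=tp, fp=fp, n_excluded=n_excluded)
    fn = len((in_frame_assessed - idx_pos) & ref_pos)
    tn = len((in_frame_assessed - idx_pos) - ref_pos)
    return ContingencyTable(tp=tp, fp=fp, fn=fn, tn=tn, n_excluded=n_excluded)


def predictive_values(
    table: ContingencyTable, prevalence_pi: float | None = None
) -> PredictiveValues:
    """Compute PPV/NPV/sensitivity/specificity from a contingency table.

    Rates whose denominators are empty (or undefined under an ascertained
    design) come back as None, never as zero.  When ``prevalence_pi`` is
    given and sensitivity/specificity are computable, PPV/NPV restated at
    that prevalence are attached.
    """
    tp, fp, fn, tn = table.tp, table.fp, table.fn, table.tn
    ppv = tp / (tp + fp) if (tp + fp) > 0 else None
    if ppv is None:
        raise DegenerateTableError("no index-positive participants: PPV undefined")
    npv = tn / (tn + fn) if (fn is not None and tn is not None and (tn + fn) > 0) else None
    sens = tp / (tp + fn) if (fn is not None and (tp + fn) > 0) else None
    spec = tn / (tn + fp) if (tn is not None and (tn + fp) > 0) else None
    pv = PredictiveValues(ppv=ppv, npv=npv, sensitivity=sens, specificity=spec)
    if prevalence_pi is not None and sens is not None and spec is not None:
        pv.ppv_adjusted, pv.npv_adjusted = prevalence_adjust(sens, spec, prevalence_pi)
        pv.prevalence_pi = prevalence_pi
    return pv


def prevalence_adjust(sensitivity: float, specificity: float, pi: float) -> tuple[float, float]:
    """Restate PPV and NPV at population point prevalence ``pi``.

    Bayes' rule on the error rates:
    ppv = sens*pi / (sens*pi + (1-spec)(1-pi));
    npv = spec*(1-pi) / (spec*(1-pi) + (1-sens)*pi).
    """
    for name, v in (("sensitivity", sensitivity), ("specificity", specificity), ("pi", pi)):
        if not 0.0 < v < 1.0:
            if name != "pi" and v == 1.0:
                continue  # perfect rates are admissible boundary cases
            raise ValueError(f"{name} must lie in (0, 1), got {v}")
    ppv_adj = sensitivity * pi / (sensitivity * pi + (1.0 - specificity) * (1.0 - pi))
    npv_adj = (
        specificity * (1.0 - pi)
        / (specificity * (1.0 - pi) + (1.0 - sensitivity) * pi)
    )
    return ppv_adj, npv_adj


def ppv_table(cohort: CohortTable, reference_source: str = "research_interview") -> pd.DataFrame:
    """Self-report PPV report: one row per subtype x reference-ladder step.

    For each self-report subtype the index set is {SZ}; the reference set
    widens along :data:`CATEGORY_LADDER`.  ``total`` is the number of
    index-positive, reference-assessed participants, ``concordant``/
    ``discordant`` the tp/fp cells, and ``ppv`` the raw ratio with a
    2-decimal rounding alongside.
    """
    rows = []
    for subtype in SELF_REPORT_SUBTYPES:
        for label, ref_set in CATEGORY_LADDER:
            try:
                tab = build_contingency(
                    cohort, subtype, {"SZ"}, reference_source, ref_set,
                    restrict_to_index_positive=True,
                )
            except DegenerateTableError:
                continue
            ppv = tab.tp / (tab.tp + tab.fp)
            rows.append(
                {
                    "self_report_method": subtype,
                    "reference_diagnosis": label,
                    "total": tab.tp + tab.fp,
                    "concordant": tab.tp,
                    "discordant": tab.fp,
                    "ppv": ppv,
                    "ppv_2dp": round(ppv, 2),
                }
            )
    return pd.DataFrame(rows)


def simulate_predictive_values(
    sensitivity: float, specificity: float, pi: float, n: int, seed: int
) -> tuple[float, float]:
    """Monte-Carlo check of the prevalence restatement.

    Draws ``n`` individuals at prevalence ``pi``, applies a test with the
    given error rates, and tabulates empirical PPV and NPV.
    """
    import numpy as np

    rng = np.random.default_rng(seed)
    disease = rng.random(n) < pi
    u = rng.random(n)
    positive = np.where(disease, u < sensitivity, u < 1.0 - specificity)
    tp = int(np.sum(positive & disease))
    fp = int(np.sum(positive & ~disease))
    tn = int(np.sum(~positive & ~disease))
    fn = int(np.sum(~positive & disease))
    return tp / (tp + fp), tn / (tn + fn)


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal rounding with ties away from zero (as printed tables round)."""
    factor = 10.0 ** ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)
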