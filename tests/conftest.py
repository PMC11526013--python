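import numpy as np
import pandas as pd
import pytest

from dxprs.datatypes import PARTICIPANT_COLUMNS, RECORD_COLUMNS, CohortTable, GenotypeMatrix


def make_cohort(records, participant_ids=None):
    """CohortTable from (pid, source, category, count) tuples."""
    rec = pd.DataFrame(records, columns=RECORD_COLUMNS)
    if participant_ids is None:
        participant_ids = list(dict.fromkeys(rec["participant_id"]))
    parts = pd.DataFrame({"participant_id": [str(p) for p in participant_ids]})
    for col in PARTICIPANT_COLUMNS[1:]:
        parts[col] = np.nan
    return CohortTable(parts, rec)


def make_genotypes(dosages, chromosome=None, position=None, freq=None):
    """GenotypeMatrix from a dense array with auto-generated metadata."""
    dosages = np.asarray(dosages, float)
    n, m = dosages.shape
    variants = pd.DataFrame(
        {
            "variant_id": [f"v{j}" for j in range(m)],
            "chromosome": chromosome if chromosome is not None else ["1"] * m,
            "position": position if position is not None else np.arange(1, m + 1) * 1000,
            "allele_effect": "A",
            "allele_other": "G",
            "frequency_effect_allele": freq if freq is not None else np.nan,
        }
    )
    return GenotypeMatrix(dosages, variants, [f"i{i}" for i in range(n)])


# Published self-report / research-interview concordance counts: for each
# self-report subtype, (n with research SZ, SA-D, other psychotic, anything
# else) among index-positive interviewed participants.
LADDER_COUNTS = {
    "self_report_lifetime": (190, 32, 16, 35),   # total 273 -> 0.70/0.81/0.87
    "self_report_current": (176, 26, 13, 24),    # total 239 -> 0.74/0.85/0.90
    "self_report_opinion": (77, 7, 3, 15),       # total 102 -> 0.75/0.82/0.85
}


@pytest.fixture(scope="session")
def ladder_cohort():
    """Cohort engineered to reproduce the published self-report PPV ladder."""
    records = []
    pid = 0
    for subtype, counts in LADDER_COUNTS.items():
        for cat, k in zip(("SZ", "SA_D", "OTHER_PSYCHOTIC", "MOOD"), counts):
            for _ in range(k):
                pid += 1
                records.append((f"p{pid}", subtype, "SZ", 1))
                records.append((f"p{pid}", "research_interview", cat, 1))
    return make_cohort(records)


@pytest.fixture(scope="session")
def hwe_genotypes():
    """Hard-call matrix in rough Hardy-Weinberg proportions, p ~ 0.3."""
    rng = np.random.default_rng(7)
    hap = rng.random((200, 2, 30)) < 0.3
    return make_genotypes(hap.sum(axis=1).astype(float))
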