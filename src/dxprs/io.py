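"""Readers and writers for the external formats the pipeline touches.

Genotypes come in as VCF 4.x (GT or DS fields, biallelic records only) or
as a transparent dosage TSV (header row of variant ids, one row per
individual, literal ``NA`` for missing).  Summary statistics and cohort
tables are TSV with configurable column names.  All writers round-trip
bit-faithfully through the corresponding reader.
"""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    PARTICIPANT_COLUMNS,
    RECORD_COLUMNS,
    SUMSTATS_COLUMNS,
    VARIANT_COLUMNS,
    CohortTable,
    GenotypeMatrix,
    SchemaError,
    SummaryStats,
)

NA = "NA"

#: Default summary-statistics column dialect; override via ``columns=``.
SUMSTATS_DIALECT = {
    "variant_id": "ID",
    "chromosome": "CHR",
    "position": "POS",
    "allele_effect": "A1",
    "allele_other": "A2",
    "beta": "BETA",
    "odds_ratio": "OR",
    "se": "SE",
    "p": "P",
    "frequency_effect_allele": "FREQ",
}


# ---------------------------------------------------------------------------
# genotypes


def read_genotypes(path, format: str = "dosage_tsv") -> GenotypeMatrix:
    """Read genotype dosages from ``vcf`` or ``dosage_tsv``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "vcf":
        return _read_vcf(path)
    if format == "dosage_tsv":
        return _read_dosage_tsv(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    individual_ids = list(vcf.samples)
    rows = []
    dosage_rows = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise SchemaError(
                f"multi-allelic record {rec.ID or rec.CHROM + ':' + str(rec.POS)!s} "
                "must be decomposed before import"
            )
        fmts = rec.FORMAT
        if "DS" in fmts:
            ds = np.asarray(rec.format("DS"), dtype=float).reshape(-1)
            ds = np.where((ds < 0) | (ds > 2), np.nan, ds)
        else:
            gt = np.asarray(rec.genotype.array())[:, :2].astype(float)
            gt[gt < 0] = np.nan
            ds = gt.sum(axis=1)
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}"
        rows.append((vid, str(rec.CHROM), int(rec.POS), rec.ALT[0], rec.REF, np.nan))
        dosage_rows.append(ds)
    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    dosages = (
        np.array(dosage_rows, dtype=float).T
        if dosage_rows
        else np.empty((len(individual_ids), 0))
    )
    return GenotypeMatrix(dosages, variants, individual_ids)


def _read_dosage_tsv(path: Path) -> GenotypeMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if header[0] != "individual_id":
        raise SchemaError(f"{path}: first column must be 'individual_id'")
    variant_ids = header[1:]
    meta = {}
    individual_ids: list[str] = []
    dosage_rows: list[list[float]] = []
    with open(path) as fh:
        fh.readline()
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise SchemaError(f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}")
            key = fields[0]
            if key.startswith("#"):
                meta[key[1:]] = fields[1:]
                continue
            individual_ids.append(key)
            row = []
            for col, tok in enumerate(fields[1:], start=2):
                if tok == NA:
                    row.append(math.nan)
                    continue
                try:
                    val = float(tok)
                except ValueError:
                    raise SchemaError(f"{path}:{lineno}: malformed dosage {tok!r}") from None
                if not 0.0 <= val <= 2.0:
                    raise SchemaError(f"{path}:{lineno}: dosage {val} outside [0, 2]")
                row.append(val)
            dosage_rows.append(row)
    expected_meta = ["chromosome", "position", "allele_effect", "allele_other"]
    if all(k in meta for k in expected_meta):
        variants = pd.DataFrame(
            {
                "variant_id": variant_ids,
                "chromosome": meta["chromosome"],
                "position": [int(x) for x in meta["position"]],
                "allele_effect": meta["allele_effect"],
                "allele_other": meta["allele_other"],
                "frequency_effect_allele": np.nan,
            }
        )
    else:
        # bare matrix: synthesise placeholder metadata from the ids
        variants = pd.DataFrame(
            {
                "variant_id": variant_ids,
                "chromosome": "0",
                "position": np.arange(1, len(variant_ids) + 1),
                "allele_effect": "A",
                "allele_other": "B",
                "frequency_effect_allele": np.nan,
            }
        )
    dosages = (
        np.array(dosage_rows, dtype=float)
        if dosage_rows
        else np.empty((0, len(variant_ids)))
    )
    return GenotypeMatrix(dosages, variants, individual_ids)


def write_dosage_tsv(G: GenotypeMatrix, path) -> None:
    """Write a genotype matrix as dosage TSV with variant metadata rows."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("individual_id\t" + "\t".join(G.variants["variant_id"]) + "\n")
        for col in ("chromosome", "position", "allele_effect", "allele_other"):
            fh.write("#" + col + "\t" + "\t".join(str(x) for x in G.variants[col]) + "\n")
        for i, iid in enumerate(G.individual_ids):
            toks = [
                NA if math.isnan(d) else repr(d) if d != int(d) else str(int(d))
                for d in G.dosages[i]
            ]
            fh.write(iid + "\t" + "\t".join(toks) + "\n")


def write_vcf(G: GenotypeMatrix, path) -> None:
    """Write hard-call/dosage genotypes as a minimal plain-text VCF 4.2."""
    path = Path(path)
    order = np.lexsort((G.variants["position"], G.variants["chromosome"]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(G.variants["chromosome"].iloc[order]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Effect-allele dosage">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(G.individual_ids)
            + "\n"
        )
        for j in order:
            v = G.variants.iloc[j]
            toks = [
                "." if math.isnan(d) else f"{d:g}" for d in G.dosages[:, j]
            ]
            fh.write(
                f"{v.chromosome}\t{v.position}\t{v.variant_id}\t{v.allele_other}\t"
                f"{v.allele_effect}\t.\t.\t.\tDS\t" + "\t".join(toks) + "\n"
            )


# ---------------------------------------------------------------------------
# summary statistics


def read_sumstats(path, columns: dict | None = None) -> SummaryStats:
    """Read a summary-statistics TSV.

    ``columns`` maps internal names to file column names (see
    :data:`SUMSTATS_DIALECT`); a ``beta`` or an ``odds_ratio`` column must
    be present — odds ratios are converted to log-odds effect sizes.
    """
    path = Path(path)
    dial = dict(SUMSTATS_DIALECT, **(columns or {}))
    df = pd.read_csv(path, sep="\t", dtype={dial["chromosome"]: str})
    required = ["variant_id", "chromosome", "position", "allele_effect", "allele_other", "se", "p"]
    missing = [dial[k] for k in required if dial[k] not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    out = pd.DataFrame(
        {k: df[dial[k]] for k in required}
    )
    if dial["beta"] in df.columns:
        out["effect_size"] = df[dial["beta"]].astype(float)
    elif dial["odds_ratio"] in df.columns:
        orv = df[dial["odds_ratio"]].astype(float)
        if (orv <= 0).any():
            raise ValueError(f"{path}: non-positive odds ratio at row {int(np.argmax(orv <= 0))}")
        out["effect_size"] = np.log(orv)
    else:
        raise SchemaError(f"{path}: need a {dial['beta']} or {dial['odds_ratio']} column")
    out["frequency_effect_allele"] = (
        df[dial["frequency_effect_allele"]].astype(float)
        if dial["frequency_effect_allele"] in df.columns
        else np.nan
    )
    return SummaryStats(out[SUMSTATS_COLUMNS])


def write_sumstats(ss: SummaryStats, path, columns: dict | None = None) -> None:
    dial = dict(SUMSTATS_DIALECT, **(columns or {}))
    t = ss.table
    out = pd.DataFrame(
        {
            dial["variant_id"]: t["variant_id"],
            dial["chromosome"]: t["chromosome"],
            dial["position"]: t["position"],
            dial["allele_effect"]: t["allele_effect"],
            dial["allele_other"]: t["allele_other"],
            dial["beta"]: t["effect_size"],
            dial["se"]: t["se"],
            dial["p"]: t["p"],
            dial["frequency_effect_allele"]: t["frequency_effect_allele"],
        }
    )
    out.to_csv(path, sep="\t", index=False, na_rep=NA)


# ---------------------------------------------------------------------------
# cohort


def read_cohort(path) -> CohortTable:
    """Read a long-format cohort TSV (one row per participant-record).

    Participants without diagnosis records carry a single row with empty
    ``source``/``category`` fields.
    """
    df = pd.read_csv(path, sep="\t", dtype={"participant_id": str}, na_values=[NA], keep_default_na=False)
    missing = [c for c in PARTICIPANT_COLUMNS + ["source", "category", "count"] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    participants = (
        df[PARTICIPANT_COLUMNS].drop_duplicates(subset="participant_id").reset_index(drop=True)
    )
    has_rec = (df["source"].astype(str) != "") & df["source"].notna()
    records = df.loc[has_rec, RECORD_COLUMNS].copy()
    if len(records):
        records["count"] = records["count"].astype(float).astype(int)
    records = records.reset_index(drop=True)
    return CohortTable(participants, records)


def write_cohort(cohort: CohortTable, path) -> None:
    parts = cohort.participants
    recs = cohort.records
    rows = []
    grouped = dict(iter(recs.groupby("participant_id"))) if len(recs) else {}
    for _, p in parts.iterrows():
        sub = grouped.get(p["participant_id"])
        if sub is None or not len(sub):
            rows.append({**p.to_dict(), "source": "", "category": "", "count": ""})
        else:
            for _, r in sub.iterrows():
                rows.append(
                    {**p.to_dict(), "source": r["source"], "category": r["category"], "count": int(r["count"])}
                )
    pd.DataFrame(rows, columns=PARTICIPANT_COLUMNS + ["source", "category", "count"]).to_csv(
        path, sep="\t", index=False, na_rep=NA
    )


# ---------------------------------------------------------------------------
# run manifest


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, entries: dict, config: dict, status: dict) -> None:
    """Write a JSON run manifest: file hashes, config echo, stage status."""
    from . import __version__

    manifest = {
        "version": __version__,
        "config": config,
        "stages": status,
        "outputs": {str(k): file_sha256(v) for k, v in entries.items()},
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
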