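"""Ingestion of FAERS- and JADER-dialect quarterly archives into a CaseSet.

FAERS quarters are ``$``-delimited ASCII tables (DEMO/DRUG/REAC mandatory,
INDI/OUTC optional, plus a deleted-case list from 2019Q1 on). JADER
quarters are CSV tables (demo/drug/reac) in a caller-specified encoding,
Shift-JIS (cp932) by default. Both dialects land in the same
:class:`~pvsignal.model.CaseSet` so downstream counting is source-agnostic.

Cleaning follows the standard FAERS practice: within each CASEID keep the
report with the most recent FDA receipt date, break ties by the largest
PRIMARYID, then drop any case named on the deleted-reports list.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dates import parse_partial_date
from .model import (
    CaseSet,
    DRUG_COLUMNS,
    EVENT_COLUMNS,
    OUTCOME_CODES,
    REPORT_COLUMNS,
    normalize_term,
)

log = logging.getLogger(__name__)

__all__ = [
    "RawTables",
    "parse_faers_quarter",
    "parse_jader_quarter",
    "deduplicate",
    "build_caseset",
    "filter_cohort",
]

# FAERS occupation codes that count as health professionals
_HEALTH_PROF = {"MD", "PH", "HP", "OT", "RN"}

# age-unit codes -> factor converting to years
_AGE_TO_YEARS = {"YR": 1.0, "DEC": 10.0, "MON": 1 / 12.0, "WK": 1 / 52.0,
                 "DY": 1 / 365.25, "HR": 1 / 8766.0}

_JADER_ROLE = {"被疑薬": "PS", "併用薬": "C", "相互作用": "I"}
_JADER_SEX = {"女性": "F", "男性": "M"}


@dataclass
class RawTables:
    """Typed per-quarter tables before deduplication and linkage."""

    reports: pd.DataFrame
    drugs: pd.DataFrame
    events: pd.DataFrame
    deleted_case_ids: set[str] = field(default_factory=set)
    n_malformed: int = 0


def _read_dollar(path: Path, required: tuple[str, ...]) -> tuple[pd.DataFrame, int]:
    """Read one $-delimited FAERS table; malformed rows are counted, not fatal."""
    bad: list = []

    def _on_bad(row):  # pragma: no cover - exercised via malformed fixtures
        bad.append(row)
        return None

    df = pd.read_csv(path, sep="$", dtype=str, keep_default_na=False,
                     engine="python", on_bad_lines=_on_bad)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: unparseable header, missing columns {missing}")
    if bad:
        log.warning("%s: skipped %d malformed rows", path.name, len(bad))
    return df, len(bad)


def _find_file(path: Path, stem: str, quarter: str = "") -> Path | None:
    """Locate one FAERS table file; prefer a quarter-labelled name when
    several quarters share the directory."""
    hits = sorted(p for p in path.iterdir()
                  if p.name.upper().startswith(stem.upper()) and p.suffix.lower() == ".txt")
    if len(hits) > 1 and quarter:
        labelled = [p for p in hits if quarter.upper() in p.name.upper()]
        if labelled:
            return labelled[0]
    return hits[0] if hits else None


def _quarter_from_fda_dt(raw: str) -> str:
    d = parse_partial_date(raw)
    if d.year is None or d.month is None:
        return ""
    return f"{d.year}Q{(d.month - 1) // 3 + 1}"


def parse_faers_quarter(path: str | Path, quarter: str) -> RawTables:
    """Parse one FAERS quarterly directory into typed raw tables.

    DEMO, DRUG and REAC are mandatory; OUTC and INDI enrich the report
    rows when present; the deleted-case list (DELETE*/DELETED*) is read
    for quarters from 2019Q1 onward.
    """
    path = Path(path)
    tables: dict[str, pd.DataFrame] = {}
    n_bad = 0
    for stem, required in (("DEMO", ("primaryid", "caseid", "fda_dt", "sex")),
                           ("DRUG", ("primaryid", "role_cod", "drugname")),
                           ("REAC", ("primaryid", "pt"))):
        f = _find_file(path, stem, quarter)
        if f is None:
            raise FileNotFoundError(f"missing mandatory FAERS file {stem}*.txt in {path}")
        tables[stem], nb = _read_dollar(f, required)
        n_bad += nb

    demo = tables["DEMO"]
    age_num = pd.to_numeric(demo.get("age", ""), errors="coerce")
    age_factor = demo.get("age_cod", pd.Series("", index=demo.index)).str.upper().map(_AGE_TO_YEARS)
    age_years = age_num * age_factor
    wt_num = pd.to_numeric(demo.get("wt", ""), errors="coerce")
    wt_cod = demo.get("wt_cod", pd.Series("", index=demo.index)).str.upper()
    weight = np.where(wt_cod.isin(["LBS", "LB"]), wt_num * 0.453592,
                      np.where(wt_cod.isin(["KG", ""]), wt_num, np.nan))
    occp = demo.get("occp_cod", pd.Series("", index=demo.index)).str.upper()
    reporter = np.where(occp.isin(_HEALTH_PROF), "health_professional",
                        np.where(occp == "CN", "consumer", "unknown"))

    reports = pd.DataFrame({
        "report_id": demo["primaryid"].str.strip(),
        "case_id": demo["caseid"].str.strip(),
        "receipt_date": demo["fda_dt"].map(lambda s: str(parse_partial_date(s))),
        "sex": demo["sex"].str.strip().str.upper().where(
            demo["sex"].str.strip().str.upper().isin(["F", "M"]), "unknown"),
        "age_years": age_years,
        "weight_kg": weight,
        "country": demo.get("reporter_country", pd.Series("", index=demo.index)).str.strip().str.upper(),
        "reporter": reporter,
        "outcomes": "",
        "quarter": quarter,
        "source": "FAERS",
        "indication": "",
    })

    # multiple DEMO rows per PRIMARYID: take the first and log
    if reports["report_id"].duplicated().any():
        n_dup = int(reports["report_id"].duplicated().sum())
        log.warning("%s DEMO: %d extra rows for already-seen PRIMARYIDs; keeping first", quarter, n_dup)
        reports = reports.drop_duplicates("report_id", keep="first")

    outc_file = _find_file(path, "OUTC", quarter)
    if outc_file is not None:
        outc, nb = _read_dollar(outc_file, ("primaryid", "outc_cod"))
        n_bad += nb
        outc["outc_cod"] = outc["outc_cod"].str.strip().str.upper()
        outc = outc[outc["outc_cod"].isin(OUTCOME_CODES)]
        agg = outc.groupby("primaryid")["outc_cod"].apply(
            lambda s: ";".join(sorted(set(s))))
        reports["outcomes"] = reports["report_id"].map(agg).fillna("")

    indi_file = _find_file(path, "INDI", quarter)
    if indi_file is not None:
        indi, nb = _read_dollar(indi_file, ("primaryid", "indi_pt"))
        n_bad += nb
        first = indi.groupby("primaryid")["indi_pt"].first().map(normalize_term)
        reports["indication"] = reports["report_id"].map(first).fillna("")

    drug = tables["DRUG"]
    drugs = pd.DataFrame({
        "report_id": drug["primaryid"].str.strip(),
        "drug_name": drug["drugname"].map(normalize_term),
        "role": drug["role_cod"].str.strip().str.upper(),
        "start_date": drug.get("start_dt", pd.Series("", index=drug.index)).map(
            lambda s: str(parse_partial_date(s))),
    })

    reac = tables["REAC"]
    events = pd.DataFrame({
        "report_id": reac["primaryid"].str.strip(),
        "pt": reac["pt"].map(normalize_term),
        "onset_date": reac.get("event_dt", pd.Series("", index=reac.index)).map(
            lambda s: str(parse_partial_date(s))),
    })

    deleted: set[str] = set()
    year, q = int(quarter[:4]), quarter[4:]
    if (year, q) >= (2019, "Q1"):
        del_file = _find_file(path, "DELET", quarter)
        if del_file is not None:
            lines = del_file.read_text().splitlines()
            deleted = {ln.strip() for ln in lines[1:] if ln.strip()}  # first line is header

    return RawTables(reports, drugs, events, deleted, n_bad)


def parse_jader_quarter(path: str | Path, encoding: str = "cp932") -> RawTables:
    """Parse one JADER quarterly directory of CSV tables.

    The JADER role vocabulary (被疑薬/併用薬/相互作用) is mapped onto
    {PS, C, I}; exact duplicate rows in the DRUG and REAC tables are
    collapsed. The case number serves as both report and case identifier
    (JADER has no deleted-list mechanism).
    """
    path = Path(path)

    def read(stem: str, required: tuple[str, ...]) -> pd.DataFrame:
        hits = sorted(p for p in path.iterdir()
                      if p.name.lower().startswith(stem) and p.suffix.lower() == ".csv")
        if not hits:
            raise FileNotFoundError(f"missing mandatory JADER file {stem}*.csv in {path}")
        f = hits[0]
        try:
            df = pd.read_csv(f, dtype=str, keep_default_na=False, encoding=encoding)
        except UnicodeDecodeError as e:
            raise ValueError(
                f"{f.name}: undecodable bytes at offset {e.start} with encoding {encoding!r}") from e
        df.columns = [c.strip() for c in df.columns]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"{f.name}: unparseable header, missing columns {missing}")
        return df

    demo = read("demo", ("識別番号", "性別"))
    drug = read("drug", ("識別番号", "医薬品の関与", "医薬品（一般名）"))
    reac = read("reac", ("識別番号", "有害事象"))

    def col(df: pd.DataFrame, name: str) -> pd.Series:
        return df[name] if name in df.columns else pd.Series("", index=df.index)

    receipt = col(demo, "報告日").map(lambda s: str(parse_partial_date(s)))
    age = col(demo, "年齢").str.extract(r"(\d+)", expand=False)
    reporter_raw = col(demo, "報告者職種")
    reports = pd.DataFrame({
        "report_id": demo["識別番号"].str.strip(),
        "case_id": demo["識別番号"].str.strip(),
        "receipt_date": receipt,
        "sex": demo["性別"].str.strip().map(_JADER_SEX).fillna("unknown"),
        "age_years": pd.to_numeric(age, errors="coerce"),
        "weight_kg": pd.to_numeric(col(demo, "体重").str.extract(r"(\d+)", expand=False),
                                   errors="coerce"),
        "country": "JP",
        "reporter": np.where(reporter_raw.str.contains("医|薬", regex=True, na=False),
                             "health_professional",
                             np.where(reporter_raw.str.strip() == "消費者", "consumer", "unknown")),
        "outcomes": "",
        "quarter": receipt.map(_quarter_from_fda_dt),
        "source": "JADER",
        "indication": col(demo, "原疾患").map(normalize_term),
    })
    if reports["report_id"].duplicated().any():
        log.warning("JADER demo: duplicate case numbers; keeping first row each")
        reports = reports.drop_duplicates("report_id", keep="first")

    drug = drug.drop_duplicates()  # exact-row dedup, per cleaning protocol
    drugs = pd.DataFrame({
        "report_id": drug["識別番号"].str.strip(),
        "drug_name": drug["医薬品（一般名）"].map(normalize_term),
        "role": drug["医薬品の関与"].str.strip().map(_JADER_ROLE).fillna("C"),
        "start_date": col(drug, "投与開始日").map(lambda s: str(parse_partial_date(s))),
    })

    reac = reac.drop_duplicates()
    events = pd.DataFrame({
        "report_id": reac["識別番号"].str.strip(),
        "pt": reac["有害事象"].map(normalize_term),
        "onset_date": col(reac, "有害事象の発現日").map(lambda s: str(parse_partial_date(s))),
    })

    return RawTables(reports, drugs, events, set(), 0)


def deduplicate(reports: pd.DataFrame, deleted_case_ids: set[str] | None = None) -> pd.DataFrame:
    """One report per case: latest receipt date, then largest report id.

    Receipt dates are the zero-padded partial-date strings produced at
    parse time; lexicographic order on them equals the (year, month, day)
    order with missing components smallest. Report ids compare numerically
    when possible; non-numeric ids fall back to lexicographic order (logged).
    Cases on the deleted list are removed after the per-case selection.
    """
    if reports.empty:
        return reports.copy()
    df = reports.copy()
    num_id = pd.to_numeric(df["report_id"], errors="coerce")
    if num_id.isna().any():
        log.warning("%d non-numeric report ids; tie-breaking lexicographically",
                    int(num_id.isna().sum()))
    df["_num_id"] = num_id.fillna(-np.inf)
    df = df.sort_values(["case_id", "receipt_date", "_num_id", "report_id"],
                        kind="mergesort")
    kept = df.groupby("case_id", sort=False).tail(1).drop(columns="_num_id")
    if deleted_case_ids:
        kept = kept[~kept["case_id"].isin(deleted_case_ids)]
    return kept.sort_values("report_id", kind="mergesort").reset_index(drop=True)


def build_caseset(raw: RawTables | list[RawTables],
                  vocabulary: dict[str, str] | None = None) -> CaseSet:
    """Concatenate raw quarters, deduplicate, and link into a CaseSet.

    Drug/event rows pointing at reports dropped by deduplication (or at
    case numbers absent from DEMO) are removed; orphans that never matched
    any report are logged.
    """
    raws = raw if isinstance(raw, list) else [raw]
    reports = pd.concat([r.reports for r in raws], ignore_index=True)
    drugs = pd.concat([r.drugs for r in raws], ignore_index=True)
    events = pd.concat([r.events for r in raws], ignore_index=True)
    deleted: set[str] = set().union(*(r.deleted_case_ids for r in raws))

    known = set(reports["report_id"])
    for name, tbl in (("drug", drugs), ("event", events)):
        orphans = ~tbl["report_id"].isin(known)
        if orphans.any():
            log.warning("dropping %d %s rows with unknown report ids", int(orphans.sum()), name)

    retained = deduplicate(reports, deleted)
    keep = set(retained["report_id"])
    cs = CaseSet(
        reports=retained,
        drugs=drugs[drugs["report_id"].isin(keep)],
        events=events[events["report_id"].isin(keep)],
        vocabulary=dict(vocabulary or {}),
    )
    cs.validate()
    return cs


def filter_cohort(caseset: CaseSet, sex: str = "F") -> CaseSet:
    """Restrict the report universe to one sex.

    Requesting ``F`` (the default analysis population here) drops reports
    with missing, unknown or inconsistent sex outright. Exposure to the
    drug of interest is *not* decided here: background reports must stay
    in the set for contingency counting.
    """
    keep = caseset.reports.loc[caseset.reports["sex"] == sex, "report_id"]
    if keep.empty:
        warnings.warn(f"sex filter {sex!r} leaves an empty CaseSet", stacklevel=2)
    return caseset.subset(keep)
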