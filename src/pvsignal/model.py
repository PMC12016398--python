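"""Common in-memory model for cleaned spontaneous-report data.

A :class:`CaseSet` is the linked, deduplicated universe on which all
counting is done: one ``reports`` row per retained case, one ``drugs`` row
per drug mention, one ``events`` row per reported preferred term (PT), plus
the user-supplied PT -> system-organ-class (SOC) vocabulary. Tables are
plain pandas DataFrames so every downstream step (contingency counting,
signal statistics, onset analysis) is a vectorised operation.
"""
from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "CaseSet",
    "normalize_term",
    "REPORT_COLUMNS",
    "DRUG_COLUMNS",
    "EVENT_COLUMNS",
    "OUTCOME_CODES",
    "DRUG_ROLES",
]

#: FAERS serious-outcome codes: hospitalization, life-threatening,
#: disability, death, congenital anomaly, other serious, required intervention.
OUTCOME_CODES = ("HO", "LT", "DS", "DE", "CA", "OT", "RI")

#: Drug role codes: primary suspect, secondary suspect, concomitant, interaction.
DRUG_ROLES = ("PS", "SS", "C", "I")

REPORT_COLUMNS = [
    "report_id", "case_id", "receipt_date", "sex", "age_years", "weight_kg",
    "country", "reporter", "outcomes", "quarter", "source", "indication",
]
DRUG_COLUMNS = ["report_id", "drug_name", "role", "start_date"]
EVENT_COLUMNS = ["report_id", "pt", "onset_date"]

_WS = re.compile(r"\s+")

_QUARTER = re.compile(r"^(19\d\d|20\d\d|2100)Q[1-4]$")


def normalize_term(term: object) -> str:
    """Normalize a drug name or event term: uppercase, trim, collapse spaces."""
    if term is None or (isinstance(term, float) and pd.isna(term)):
        return ""
    return _WS.sub(" ", str(term).strip()).upper()


def _empty(columns: list[str]) -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=object) for c in columns})


@dataclass
class CaseSet:
    """Linked report/drug/event tables plus the PT -> SOC vocabulary.

    Invariants (checked by :meth:`validate`): report ids are unique, no two
    reports share a case id, and every drug/event row resolves to a
    retained report.
    """

    reports: pd.DataFrame = field(default_factory=lambda: _empty(REPORT_COLUMNS))
    drugs: pd.DataFrame = field(default_factory=lambda: _empty(DRUG_COLUMNS))
    events: pd.DataFrame = field(default_factory=lambda: _empty(EVENT_COLUMNS))
    vocabulary: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.reports = self.reports.reset_index(drop=True)
        self.drugs = self.drugs.reset_index(drop=True)
        self.events = self.events.reset_index(drop=True)

    @property
    def n_reports(self) -> int:
        return len(self.reports)

    def validate(self) -> None:
        rep = self.reports
        if rep["report_id"].duplicated().any():
            dup = rep.loc[rep["report_id"].duplicated(), "report_id"].iloc[0]
            raise ValueError(f"duplicate report_id: {dup!r}")
        if rep["case_id"].duplicated().any():
            dup = rep.loc[rep["case_id"].duplicated(), "case_id"].iloc[0]
            raise ValueError(f"two reports share case_id: {dup!r}")
        ids = set(rep["report_id"])
        for name, tbl in (("drugs", self.drugs), ("events", self.events)):
            bad = set(tbl["report_id"]) - ids
            if bad:
                raise ValueError(f"{name} rows reference unknown reports: {sorted(bad)[:5]}")
        bad_q = [q for q in rep["quarter"].dropna().unique() if q and not _QUARTER.match(str(q))]
        if bad_q:
            raise ValueError(f"malformed quarter labels: {bad_q[:5]}")

    def subset(self, report_ids) -> "CaseSet":
        """Restrict to the given report ids (drug/event rows follow)."""
        keep = set(report_ids)
        return CaseSet(
            reports=self.reports[self.reports["report_id"].isin(keep)].copy(),
            drugs=self.drugs[self.drugs["report_id"].isin(keep)].copy(),
            events=self.events[self.events["report_id"].isin(keep)].copy(),
            vocabulary=dict(self.vocabulary),
        )

    # -- persistence: a directory of TSV tables plus a JSON vocabulary ----
    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.reports.to_csv(path / "reports.tsv", sep="\t", index=False)
        self.drugs.to_csv(path / "drugs.tsv", sep="\t", index=False)
        self.events.to_csv(path / "events.tsv", sep="\t", index=False)
        (path / "vocabulary.json").write_text(json.dumps(self.vocabulary, indent=0))

    @classmethod
    def load(cls, path: str | Path) -> "CaseSet":
        path = Path(path)
        kw = dict(sep="\t", dtype=str, keep_default_na=False)
        reports = pd.read_csv(path / "reports.tsv", **kw)
        for col in ("age_years", "weight_kg"):
            reports[col] = pd.to_numeric(reports[col], errors="coerce")
        vocab_file = path / "vocabulary.json"
        vocab = json.loads(vocab_file.read_text()) if vocab_file.exists() else {}
        return cls(
            reports=reports,
            drugs=pd.read_csv(path / "drugs.tsv", **kw),
            events=pd.read_csv(path / "events.tsv", **kw),
            vocabulary=vocab,
        )

    def equals(self, other: "CaseSet") -> bool:
        """Order-insensitive equality of the three tables and vocabulary."""
        def canon(df: pd.DataFrame) -> pd.DataFrame:
            out = df.astype(str).sort_values(list(df.columns)).reset_index(drop=True)
            return out

        return (
            canon(self.reports).equals(canon(other.reports))
            and canon(self.drugs).equals(canon(other.drugs))
            and canon(self.events).equals(canon(other.events))
            and self.vocabulary == other.vocabulary
        )


def load_vocabulary(path: str | Path, sep: str | None = None) -> dict[str, str]:
    """Read a two-column (pt, soc) delimited text file into a mapping."""
    path = Path(path)
    df = pd.read_csv(path, sep=sep or "\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ValueError(f"vocabulary file needs two columns (pt, soc): {path}")
    pts, socs = df.iloc[:, 0], df.iloc[:, 1]
    return {normalize_term(p): normalize_term(s) for p, s in zip(pts, socs)}
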