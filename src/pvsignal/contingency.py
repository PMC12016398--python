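"""2x2 contingency tables for drug-event pairs from a CaseSet.

Counting unit: the distinct (report, term) pair. A report listing the same
preferred term twice contributes once; at SOC level a report with two PTs
in one system organ class contributes once to that class. With this unit
the drug margin a+b (the drug's total distinct report-term pairs) is the
same for every term, which is what lets one drug's thousands of PT tables
share a single background.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import pandas as pd

from .model import CaseSet, normalize_term

log = logging.getLogger(__name__)

__all__ = ["ContingencyTable", "exposed_report_ids", "count_pairs", "rollup_soc"]

UNMAPPED = "UNMAPPED"


@dataclass(frozen=True)
class ContingencyTable:
    """Cells of one drug-event 2x2 table.

    a: target drug and target event; b: target drug, other events;
    c: other drugs, target event; d: other drugs, other events.
    """

    a: int
    b: int
    c: int
    d: int
    term: str = ""
    level: str = "PT"

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError(f"negative cell in {self}")
        if self.n == 0:
            raise ValueError("empty table (N = 0)")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


def exposed_report_ids(caseset: CaseSet, target_drug: list[str], role: str | None = "PS") -> set[str]:
    """Reports naming the target drug (normalized exact match) in the given role.

    ``role=None`` accepts any role. Matching is exact after normalization —
    no substring matching, so combination products with longer names do not
    leak in.
    """
    if not target_drug:
        raise ValueError("target_drug synonym list is empty")
    synonyms = {normalize_term(s) for s in target_drug}
    d = caseset.drugs
    mask = d["drug_name"].isin(synonyms)
    if role is not None:
        mask &= d["role"] == role
    return set(d.loc[mask, "report_id"])


def _pair_tables(pairs: pd.DataFrame, exposed: set[str], level: str) -> pd.DataFrame:
    """Cells for every term from a distinct (report_id, term) pair frame."""
    is_exp = pairs["report_id"].isin(exposed)
    n_total = len(pairs)
    n_exposed = int(is_exp.sum())
    a = pairs.loc[is_exp, "term"].value_counts()
    col = pairs["term"].value_counts()  # a + c per term
    out = pd.DataFrame({"term": col.index, "level": level})
    out["a"] = a.reindex(col.index).fillna(0).astype(int).to_numpy()
    out["b"] = n_exposed - out["a"]
    out["c"] = col.to_numpy() - out["a"]
    out["d"] = n_total - n_exposed - out["c"]
    return out.sort_values(["a", "term"], ascending=[False, True], kind="mergesort").reset_index(drop=True)


def count_pairs(caseset: CaseSet, target_drug: list[str], role: str | None = "PS") -> pd.DataFrame:
    """Per-PT contingency tables (columns term, level, a, b, c, d).

    ``a`` counts distinct (report, PT) pairs among reports carrying the
    target drug in the given role; the background is every other report in
    the (already cohort-filtered) CaseSet.
    """
    exposed = exposed_report_ids(caseset, target_drug, role)
    if not exposed:
        warnings.warn("no reports exposed to the target drug; zero tables emitted",
                      stacklevel=2)
        return pd.DataFrame(columns=["term", "level", "a", "b", "c", "d"])
    ev = caseset.events
    pairs = (ev.loc[ev["pt"] != "", ["report_id", "pt"]]
             .rename(columns={"pt": "term"}).drop_duplicates())
    return _pair_tables(pairs, exposed, "PT")


def rollup_soc(caseset: CaseSet, target_drug: list[str], role: str | None = "PS",
               vocabulary: dict[str, str] | None = None) -> pd.DataFrame:
    """Per-SOC contingency tables via the PT -> SOC vocabulary.

    PTs missing from the vocabulary are collected under ``UNMAPPED`` (with
    a warning) so cell conservation still holds. An empty vocabulary is a
    hard error: SOC rollup without a mapping is meaningless.
    """
    vocab = vocabulary if vocabulary is not None else caseset.vocabulary
    if not vocab:
        raise ValueError("empty PT->SOC vocabulary; cannot roll up to SOC level")
    exposed = exposed_report_ids(caseset, target_drug, role)
    if not exposed:
        warnings.warn("no reports exposed to the target drug; zero tables emitted",
                      stacklevel=2)
        return pd.DataFrame(columns=["term", "level", "a", "b", "c", "d"])
    ev = caseset.events
    pairs = ev.loc[ev["pt"] != "", ["report_id", "pt"]].copy()
    pairs["term"] = pairs["pt"].map(vocab)
    n_unmapped = int(pairs["term"].isna().sum())
    if n_unmapped:
        missing = sorted(pairs.loc[pairs["term"].isna(), "pt"].unique())
        log.warning("%d event rows with %d PTs missing from the vocabulary, "
                    "counted under %s: %s%s", n_unmapped, len(missing), UNMAPPED,
                    missing[:5], "..." if len(missing) > 5 else "")
        pairs["term"] = pairs["term"].fillna(UNMAPPED)
    pairs = pairs[["report_id", "term"]].drop_duplicates()
    return _pair_tables(pairs, exposed, "SOC")
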