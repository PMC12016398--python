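"""Descriptive outputs: baseline characteristics and annual report trend.

Percentages are displayed to one decimal, rounded half-away-from-zero
(the convention under which 359/1096 prints as 32.8, not 32.7).
"""
from __future__ import annotations

import math

import pandas as pd

from .model import CaseSet, OUTCOME_CODES

__all__ = ["percent", "baseline", "annual_trend"]

_OUTCOME_LABEL = {"HO": "Hospitalization", "LT": "Life-threatening",
                  "DS": "Disability", "DE": "Death", "CA": "Congenital anomaly",
                  "OT": "Other serious", "RI": "Required intervention"}


def percent(count: int, total: int) -> float:
    """100*count/total to one decimal, half rounded away from zero."""
    if total <= 0:
        raise ValueError("total must be positive")
    if count > total:
        raise ValueError(f"count {count} exceeds total {total}")
    x = 100.0 * count / total
    return math.floor(x * 10 + 0.5) / 10 if x >= 0 else -math.floor(-x * 10 + 0.5) / 10


def _section(rows: list, section: str, items: list[tuple[str, int]], total: int) -> None:
    for category, n in items:
        rows.append((section, category, n, percent(n, total)))


def baseline(caseset: CaseSet) -> pd.DataFrame:
    """Baseline-characteristics table (section, category, count, percent).

    Sections: Sex; Age (<18 / 18-65 / >65 / Unknown); Weight (<50 / 50-100 /
    >100 / Unknown); top-5 countries; reporter type; outcomes (report-level
    flags, a report may count in several rows); top-5 indications.
    Percentages are against the cohort size.
    """
    rep = caseset.reports
    total = len(rep)
    if total == 0:
        return pd.DataFrame(columns=["section", "category", "count", "percent"])
    rows: list = []

    sex_counts = rep["sex"].value_counts()
    label = {"F": "Female", "M": "Male"}
    _section(rows, "Sex", [(label.get(s, "Unknown"), int(n)) for s, n in sex_counts.items()], total)

    age = rep["age_years"]
    age_items = [("< 18 years", int((age < 18).sum())),
                 ("18-65 years", int(((age >= 18) & (age <= 65)).sum())),
                 ("> 65 years", int((age > 65).sum())),
                 ("Unknown", int(age.isna().sum()))]
    _section(rows, "Age", [it for it in age_items if it[1] > 0 or it[0] == "Unknown"], total)

    wt = rep["weight_kg"]
    wt_items = [("< 50 kg", int((wt < 50).sum())),
                ("50-100 kg", int(((wt >= 50) & (wt <= 100)).sum())),
                ("> 100 kg", int((wt > 100).sum())),
                ("Unknown", int(wt.isna().sum()))]
    _section(rows, "Weight", [it for it in wt_items if it[1] > 0 or it[0] == "Unknown"], total)

    country = rep["country"].fillna("").replace("", "Unknown")
    top = country.value_counts()
    top5 = top.sort_values(ascending=False).index[:5]
    # deterministic alphabetical tie-break within equal counts
    top5 = sorted(top5, key=lambda c: (-top[c], c))
    _section(rows, "Reported Countries (top five)",
             [(c, int(top[c])) for c in top5], total)

    rep_counts = rep["reporter"].value_counts()
    rlabel = {"health_professional": "Health professionals", "consumer": "Consumer"}
    _section(rows, "Reported person",
             [(rlabel.get(r, "Unknown"), int(n)) for r, n in rep_counts.items()], total)

    flags = rep["outcomes"].fillna("")
    outcome_items = []
    for code in OUTCOME_CODES:
        n = int(flags.str.split(";").map(lambda xs: code in xs).sum())
        if n > 0:
            outcome_items.append((_OUTCOME_LABEL[code], n))
    n_none = int((flags == "").sum())
    if n_none:
        outcome_items.append(("Unknown", n_none))
    _section(rows, "Outcome", outcome_items, total)

    indi = rep["indication"].fillna("").replace("", "Unknown")
    itop = indi.value_counts()
    named = [c for c in itop.index if c != "Unknown"]
    top5i = sorted(named, key=lambda c: (-itop[c], c))[:5]
    _section(rows, "Indication (top five)", [(c, int(itop[c])) for c in top5i], total)

    return pd.DataFrame(rows, columns=["section", "category", "count", "percent"])


def annual_trend(caseset: CaseSet) -> pd.DataFrame:
    """Report counts per calendar year of receipt; missing years tallied apart."""
    rep = caseset.reports
    if rep.empty:
        return pd.DataFrame(columns=["year", "count"])
    years = rep["receipt_date"].fillna("").astype(str).str[:4]
    known = years[years.str.match(r"^\d{4}$")]
    counts = known.value_counts().sort_index()
    out = pd.DataFrame({"year": counts.index.astype(int), "count": counts.to_numpy()})
    n_missing = len(rep) - len(known)
    if n_missing:
        out = pd.concat([out, pd.DataFrame({"year": [-1], "count": [n_missing]})],
                        ignore_index=True)
    return out
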