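"""Comparator re-analysis, monotherapy subset, and signal triage.

A consensus signal can reflect the treated condition rather than the drug.
Re-running the identical detection pipeline with a same-indication
comparator separates the two: signals positive for both drugs are
"disease-expected". Signals naming terms already on the product label are
"expected"; everything else is "unexpected". The monotherapy subset
(reports naming the target drug and no other drug) removes concomitant
-medication confounding.
"""
from __future__ import annotations

from pathlib import Path

import pandas as pd

from .contingency import exposed_report_ids
from .model import CaseSet, normalize_term
from .signals import BCPNNPriors, Thresholds, detect

__all__ = ["comparator_signals", "monotherapy_subset", "triage", "load_label_terms"]

TRIAGE_CLASSES = ("expected", "disease_expected", "unexpected")


def load_label_terms(path: str | Path) -> set[str]:
    """Read a label ADR term list (one PT per line), normalized like PTs."""
    terms = {normalize_term(ln) for ln in Path(path).read_text().splitlines()}
    terms.discard("")
    return terms


def comparator_signals(caseset: CaseSet, comparator_drug: list[str],
                       level: str = "PT", role: str | None = "PS",
                       min_count: int = 3,
                       priors: BCPNNPriors = BCPNNPriors(),
                       thresholds: Thresholds = Thresholds()) -> pd.DataFrame:
    """Signal table for the comparator drug through the identical pipeline.

    Adds a ``min_count_ok`` column marking terms with at least ``min_count``
    comparator reports (the supplementary-table convention of "no less than
    three counts"). A comparator absent from the CaseSet is a hard error.
    """
    if not exposed_report_ids(caseset, comparator_drug, role):
        raise ValueError(
            f"comparator drug {comparator_drug!r} has no reports in the CaseSet")
    table = detect(caseset, comparator_drug, level=level, role=role,
                   priors=priors, thresholds=thresholds)
    table["min_count_ok"] = table["a"] >= min_count
    return table


def monotherapy_subset(caseset: CaseSet, target_drug: list[str]) -> CaseSet:
    """Reports whose drug entries name the target drug and nothing else."""
    synonyms = {normalize_term(s) for s in target_drug}
    d = caseset.drugs
    by_report = d.groupby("report_id")["drug_name"].agg(set)
    mono = by_report[by_report.map(lambda names: bool(names) and names <= synonyms)]
    return caseset.subset(mono.index)


def triage(target_signals: pd.DataFrame, comparator_signals: pd.DataFrame,
           label_terms: set[str]) -> pd.DataFrame:
    """Classify each target consensus signal as expected / disease_expected / unexpected.

    Precedence: (1) term on the product label -> expected; (2) else
    consensus-positive for the comparator too -> disease_expected;
    (3) else -> unexpected. Only target consensus-positive terms are triaged.
    """
    if not label_terms:
        raise ValueError("label term list is empty; cannot triage signals")
    label = {normalize_term(t) for t in label_terms}
    comp_pos = set(
        comparator_signals.loc[comparator_signals["consensus"], "term"])
    rows = []
    for term in target_signals.loc[target_signals["consensus"], "term"]:
        if term in label:
            cls = "expected"
        elif term in comp_pos:
            cls = "disease_expected"
        else:
            cls = "unexpected"
        rows.append((term, cls))
    return pd.DataFrame(rows, columns=["term", "triage"])
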