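"""Synthetic FAERS- and JADER-dialect archives with known ground truth.

The generator emulates the structure that makes spontaneous-report
cleaning non-trivial — multi-table cases linked by identifiers, repeat
submissions of the same case, role-coded drug entries, partial and
inconsistent dates — while keeping the statistical content fully known:

* every report draws one primary-suspect (PS) drug; the target drug is a
  configurable (small) fraction of reports, mirroring a niche drug inside
  a large database;
* each report carries K = 1 + Poisson(lambda) event draws from a
  categorical PT distribution; for drugs with planted (drug, event,
  relative_risk) associations the planted PT's weight is multiplied by
  the relative risk and the distribution renormalised, so the expected
  disproportionality of the planted pair is known in closed form;
* onset intervals are Weibull(shape, scale) days added to the drug start
  date, then corrupted at configurable rates into month-precision or
  inconsistent dates;
* FAERS dialect: repeat submissions share the CASEID with an earlier
  FDA_DT (or the same FDA_DT and a smaller PRIMARYID), and a deleted-case
  list accompanies quarters from 2019Q1 on. JADER dialect: no deleted
  list; duplication appears as exactly repeated DRUG/REAC rows.

The returned :class:`SyntheticTruth` manifest is the oracle for ingest
round-trips, planted-signal recovery and Weibull recovery tests.
"""
from __future__ import annotations

import calendar
import dataclasses
import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["GeneratorConfig", "SyntheticTruth", "generate", "expected_cells"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic archives.

    Defaults emulate a rare drug (1% of reports) with one strongly planted
    association in a moderate vocabulary, FAERS-like event multiplicity
    (mean 2.2 distinct-ish draws per report) and an early-failure onset
    profile (Weibull shape < 1, scale ~3 weeks).
    """

    n_reports: int = 20000
    n_drugs: int = 40                  # background drugs beside target & comparator
    n_events: int = 60
    n_socs: int = 8
    target_drug: str = "GANIRELIX ACETATE"
    target_synonyms: tuple[str, ...] = ("GANIRELIX ACETATE", "ORGALUTRAN", "ANTAGON")
    comparator_drug: str = "CETRORELIX"
    comparator_synonyms: tuple[str, ...] = ("CETRORELIX", "CETROTIDE")
    exposure_fraction: float = 0.01
    comparator_fraction: float = 0.01
    planted: tuple[tuple[str, str, float], ...] = (
        ("GANIRELIX ACETATE", "EVT_OHSS", 50.0),
    )
    planted_base_prob: float = 0.002   # baseline probability of each planted PT
    events_per_report_mean: float = 1.2  # K = 1 + Poisson(mean)
    duplicate_rate: float = 0.2
    deleted_fraction: float = 0.02
    partial_date_rate: float = 0.1
    inconsistent_date_rate: float = 0.02
    monotherapy_fraction: float = 0.4
    tto_shape: float = 0.8
    tto_scale: float = 20.0
    sex_mix: tuple[tuple[str, float], ...] = (("F", 0.80), ("M", 0.17), ("UNK", 0.03))
    country_mix: tuple[tuple[str, float], ...] = (
        ("US", 0.55), ("DE", 0.16), ("FR", 0.12), ("GB", 0.09), ("JP", 0.05), ("NL", 0.03))
    reporter_mix: tuple[tuple[str, float], ...] = (("MD", 0.50), ("CN", 0.33),
                                                   ("PH", 0.16), ("LW", 0.01))
    outcome_probs: tuple[tuple[str, float], ...] = (
        ("HO", 0.33), ("OT", 0.13), ("LT", 0.014), ("DS", 0.005),
        ("DE", 0.002), ("CA", 0.001))
    age_missing_rate: float = 0.3
    weight_missing_rate: float = 0.6
    quarters: tuple[str, ...] = ("2023Q1", "2023Q2", "2023Q3", "2023Q4")
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("exposure_fraction", "comparator_fraction", "duplicate_rate",
                     "deleted_fraction", "partial_date_rate", "inconsistent_date_rate",
                     "monotherapy_fraction", "planted_base_prob",
                     "age_missing_rate", "weight_missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for drug, event, rr in self.planted:
            if rr <= 0:
                raise ValueError(f"planted relative risk must be > 0: {(drug, event, rr)}")
        if len(self.planted) > self.n_events:
            raise ValueError("more planted events than vocabulary entries")
        if self.tto_shape <= 0 or self.tto_scale <= 0:
            raise ValueError("Weibull onset parameters must be positive")

    # -- derived vocabulary ------------------------------------------------
    def event_vocabulary(self) -> list[str]:
        planted_events = [e for _, e, _ in self.planted]
        extra = [f"PT_{i:03d}" for i in range(self.n_events - len(set(planted_events)))]
        seen: dict[str, None] = dict.fromkeys(planted_events)
        for e in extra:
            seen.setdefault(e)
        return list(seen)

    def soc_mapping(self) -> dict[str, str]:
        return {pt: f"SOC_{i % self.n_socs:02d}"
                for i, pt in enumerate(self.event_vocabulary())}

    def background_drugs(self) -> list[str]:
        return [f"DRUG_{i:04d}" for i in range(self.n_drugs)]

    def base_event_probs(self) -> np.ndarray:
        """Baseline PT probabilities: planted PTs at planted_base_prob, rest uniform."""
        vocab = self.event_vocabulary()
        planted_events = {e for _, e, _ in self.planted}
        n_plain = len(vocab) - len(planted_events)
        p_planted = self.planted_base_prob
        rest = (1.0 - p_planted * len(planted_events)) / n_plain
        return np.array([p_planted if pt in planted_events else rest for pt in vocab])

    def tilted_event_probs(self, drug: str) -> np.ndarray:
        """Event distribution for reports whose PS drug is ``drug``."""
        p = self.base_event_probs().copy()
        vocab = self.event_vocabulary()
        for d, e, rr in self.planted:
            if d == drug:
                p[vocab.index(e)] *= rr
        return p / p.sum()


@dataclass
class SyntheticTruth:
    """Ground-truth manifest written next to the generated archive."""

    retained_report_ids: set[str]
    duplicate_lineage: dict[str, list[str]]
    deleted_case_ids: set[str]
    planted: list[tuple[str, str, float]]
    true_tto_params: tuple[float, float]
    monotherapy_report_ids: set[str]
    exposed_report_ids: set[str]
    expected_pair_cells: dict[str, tuple[float, float, float, float]]
    config: GeneratorConfig

    def save(self, path: str | Path) -> None:
        d = {
            "retained_report_ids": sorted(self.retained_report_ids),
            "duplicate_lineage": {k: sorted(v) for k, v in sorted(self.duplicate_lineage.items())},
            "deleted_case_ids": sorted(self.deleted_case_ids),
            "planted": list(self.planted),
            "true_tto_params": list(self.true_tto_params),
            "monotherapy_report_ids": sorted(self.monotherapy_report_ids),
            "exposed_report_ids": sorted(self.exposed_report_ids),
            "expected_pair_cells": self.expected_pair_cells,
            "config": dataclasses.asdict(self.config),
        }
        Path(path).write_text(json.dumps(d, indent=1, ensure_ascii=False))


def _phi(p: np.ndarray | float, lam: float) -> np.ndarray | float:
    """P(a report includes the PT) under K = 1 + Poisson(lam) draws with prob p."""
    return 1.0 - (1.0 - p) * np.exp(-lam * p)


def expected_cells(config: GeneratorConfig, pair: tuple[str, str],
                   female_only: bool = False) -> tuple[float, float, float, float]:
    """Closed-form expected (a, b, c, d) distinct-pair cells for a drug-event pair.

    Expectations are over the retained (post-deduplication, post-deletion)
    report universe; ``female_only`` additionally scales by the configured
    female share, matching a sex-filtered cohort.
    """
    drug, event = pair
    vocab = config.event_vocabulary()
    if event not in vocab:
        raise KeyError(f"unknown event {event!r}")
    drugs = [config.target_drug, config.comparator_drug] + config.background_drugs()
    if drug not in drugs:
        raise KeyError(f"unknown drug {drug!r}")
    lam = config.events_per_report_mean
    q_bg = (1.0 - config.exposure_fraction - config.comparator_fraction) / config.n_drugs
    q = {config.target_drug: config.exposure_fraction,
         config.comparator_drug: config.comparator_fraction}
    n = config.n_reports * (1.0 - config.deleted_fraction)
    if female_only:
        n *= dict(config.sex_mix).get("F", 0.0)

    j = vocab.index(event)
    phi_by_drug = {}
    tilt_cache = {config.target_drug: config.tilted_event_probs(config.target_drug),
                  config.comparator_drug: config.tilted_event_probs(config.comparator_drug)}
    base = config.base_event_probs()
    for g in (config.target_drug, config.comparator_drug):
        phi_by_drug[g] = _phi(tilt_cache[g], lam)
    phi_bg = _phi(base, lam)

    def row_total(g: str) -> float:
        return float(phi_by_drug.get(g, phi_bg).sum())

    def cell_a(g: str) -> float:
        return float(phi_by_drug.get(g, phi_bg)[j])

    qg = q.get(drug, q_bg)
    a = n * qg * cell_a(drug)
    row = n * qg * row_total(drug)
    col = n * (q[config.target_drug] * cell_a(config.target_drug)
               + q[config.comparator_drug] * cell_a(config.comparator_drug)
               + (1 - config.exposure_fraction - config.comparator_fraction) * phi_bg[j])
    total = n * (q[config.target_drug] * row_total(config.target_drug)
                 + q[config.comparator_drug] * row_total(config.comparator_drug)
                 + (1 - config.exposure_fraction - config.comparator_fraction)
                 * float(phi_bg.sum()))
    return a, row - a, col - a, total - row - col + a


def _quarter_days(q: str) -> tuple[_dt.date, _dt.date]:
    year, idx = int(q[:4]), int(q[5])
    m0 = (idx - 1) * 3 + 1
    last_month = m0 + 2
    return (_dt.date(year, m0, 1),
            _dt.date(year, last_month, calendar.monthrange(year, last_month)[1]))


def _fmt(d: _dt.date, precision: str = "day") -> str:
    if precision == "day":
        return f"{d.year:04d}{d.month:02d}{d.day:02d}"
    if precision == "month":
        return f"{d.year:04d}{d.month:02d}"
    return f"{d.year:04d}"


def _draw_mix(rng: np.random.Generator, mix: tuple[tuple[str, float], ...], size: int) -> np.ndarray:
    labels = [m[0] for m in mix]
    probs = np.array([m[1] for m in mix], dtype=float)
    probs = probs / probs.sum()
    return rng.choice(labels, size=size, p=probs)


def generate(config: GeneratorConfig, out: str | Path,
             dialect: str = "FAERS") -> SyntheticTruth:
    """Write one synthetic quarterly archive and return its truth manifest.

    With a fixed seed the archive is byte-identical across runs. FAERS
    dialect writes per-quarter ``$``-delimited DEMO/DRUG/REAC/OUTC/INDI
    files plus a deleted-case list; JADER dialect writes cp932 CSV
    demo/drug/reac tables.
    """
    dialect = dialect.upper()
    if dialect not in ("FAERS", "JADER"):
        raise ValueError(f"dialect must be FAERS or JADER, got {dialect!r}")
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    vocab = np.array(config.event_vocabulary())
    soc_map = config.soc_mapping()
    bg_drugs = config.background_drugs()

    # --- per-case skeleton -----------------------------------------------
    case_ids = np.array([f"C{i:07d}" for i in range(n)])
    u = rng.random(n)
    ps_cat = np.where(u < config.exposure_fraction, "T",
                      np.where(u < config.exposure_fraction + config.comparator_fraction,
                               "X", "B"))
    bg_idx = rng.integers(0, config.n_drugs, size=n)
    syn_t = rng.integers(0, len(config.target_synonyms), size=n)
    syn_x = rng.integers(0, len(config.comparator_synonyms), size=n)
    ps_name = np.empty(n, dtype=object)
    ps_canon = np.empty(n, dtype=object)
    for i in range(n):
        if ps_cat[i] == "T":
            ps_name[i] = config.target_synonyms[syn_t[i]]
            ps_canon[i] = config.target_drug
        elif ps_cat[i] == "X":
            ps_name[i] = config.comparator_synonyms[syn_x[i]]
            ps_canon[i] = config.comparator_drug
        else:
            ps_name[i] = ps_canon[i] = bg_drugs[bg_idx[i]]

    mono = rng.random(n) < config.monotherapy_fraction
    n_con = np.where(mono, 0, rng.integers(1, 3, size=n))
    con_pool = rng.integers(0, config.n_drugs, size=(n, 2))

    sex = _draw_mix(rng, config.sex_mix, n)
    country = _draw_mix(rng, config.country_mix, n)
    occp = _draw_mix(rng, config.reporter_mix, n)
    age = np.round(rng.normal(35, 6, size=n)).clip(18, 70)
    age_missing = rng.random(n) < config.age_missing_rate
    weight = np.round(rng.normal(65, 12, size=n), 1).clip(35, 140)
    weight_missing = rng.random(n) < config.weight_missing_rate
    outcome_codes = [o for o, _ in config.outcome_probs]
    outcome_flags = rng.random((n, len(outcome_codes))) < np.array(
        [p for _, p in config.outcome_probs])

    indi_pool_target = ["INFERTILITY FEMALE", "IN VITRO FERTILISATION",
                        "ASSISTED REPRODUCTIVE TECHNOLOGY", "INFERTILITY",
                        "PREVENTION OF PREMATURE OVULATION"]
    indi_pool_bg = ["HYPERTENSION", "DIABETES MELLITUS", "DEPRESSION",
                    "RHEUMATOID ARTHRITIS", "ASTHMA"]
    indi_t = rng.choice(indi_pool_target, size=n,
                        p=[0.35, 0.25, 0.2, 0.12, 0.08])
    indi_b = rng.choice(indi_pool_bg, size=n)
    indication = np.where(ps_cat == "B", indi_b, indi_t)

    quarter = rng.choice(list(config.quarters), size=n)

    # events: draw per PS category so each group shares one categorical
    k_draws = 1 + rng.poisson(config.events_per_report_mean, size=n)
    event_rows: list[tuple[int, str]] = []
    for cat, canon in (("T", config.target_drug), ("X", config.comparator_drug),
                       ("B", None)):
        members = np.flatnonzero(ps_cat == cat)
        if members.size == 0:
            continue
        probs = (config.base_event_probs() if canon is None
                 else config.tilted_event_probs(canon))
        total = int(k_draws[members].sum())
        draws = rng.choice(len(vocab), size=total, p=probs)
        owner = np.repeat(members, k_draws[members])
        event_rows.extend(zip(owner.tolist(), vocab[draws].tolist()))
    event_rows.sort()

    # dates: receipt within quarter, start within quarter, onset = start + Weibull
    q_bounds = {q: _quarter_days(q) for q in config.quarters}
    receipt = np.empty(n, dtype=object)
    start = np.empty(n, dtype=object)
    for i in range(n):
        lo, hi = q_bounds[quarter[i]]
        span = (hi - lo).days
        receipt[i] = lo + _dt.timedelta(days=int(rng.integers(0, span + 1)))
        start[i] = lo + _dt.timedelta(days=int(rng.integers(0, span + 1)))
    tto_days = np.round(config.tto_scale
                        * rng.weibull(config.tto_shape, size=n)).astype(int)
    onset = np.array([s + _dt.timedelta(days=int(t)) for s, t in zip(start, tto_days)],
                     dtype=object)
    start_prec = np.where(rng.random(n) < config.partial_date_rate, "month", "day")
    onset_prec = np.where(rng.random(n) < config.partial_date_rate, "month", "day")
    inconsistent = rng.random(n) < config.inconsistent_date_rate
    for i in np.flatnonzero(inconsistent):
        onset[i] = start[i] - _dt.timedelta(days=int(rng.integers(1, 30)))

    # duplicate submissions (FAERS) and the deleted-case list
    dup = rng.random(n) < config.duplicate_rate
    dup_same_date = rng.random(n) < 0.5  # half tie on FDA_DT, decided by PRIMARYID
    dup_lag = rng.integers(1, 90, size=n)
    deleted_mask = rng.random(n) < config.deleted_fraction
    has_2019 = any(q >= "2019Q1" for q in config.quarters)
    if dialect != "FAERS" or not has_2019:
        deleted_mask[:] = False

    base_id = 1_000_000 + np.arange(n) * 10
    kept_id = (base_id + 2).astype(str)
    dup_id = (base_id + 1).astype(str)

    exposed = {kept_id[i] if dialect == "FAERS" else case_ids[i]
               for i in np.flatnonzero((ps_cat == "T") & ~deleted_mask)}
    mono_ids = {kept_id[i] if dialect == "FAERS" else case_ids[i]
                for i in np.flatnonzero(mono & ~deleted_mask)}

    truth = SyntheticTruth(
        retained_report_ids=(
            {kept_id[i] for i in range(n) if not deleted_mask[i]}
            if dialect == "FAERS" else set(case_ids)),
        duplicate_lineage={case_ids[i]: ([dup_id[i], kept_id[i]] if dup[i] else [kept_id[i]])
                           for i in range(n)} if dialect == "FAERS" else
                          {c: [c] for c in case_ids},
        deleted_case_ids={case_ids[i] for i in np.flatnonzero(deleted_mask)},
        planted=[list(p) for p in config.planted],
        true_tto_params=(config.tto_shape, config.tto_scale),
        monotherapy_report_ids=mono_ids,
        exposed_report_ids=exposed,
        expected_pair_cells={f"{d}|{e}": expected_cells(config, (d, e))
                             for d, e, _ in config.planted},
        config=config,
    )

    events_by_report: dict[int, list[str]] = {}
    for i, pt in event_rows:
        events_by_report.setdefault(i, []).append(pt)

    if dialect == "FAERS":
        _write_faers(out, config, rng, locals())
    else:
        _write_jader(out, config, rng, locals())

    truth.save(out / "truth.json")
    (out / "vocabulary.tsv").write_text(
        "pt\tsoc\n" + "".join(f"{pt}\t{soc}\n" for pt, soc in soc_map.items()))
    return truth


def _write_faers(out: Path, config: GeneratorConfig, rng: np.random.Generator,
                 ns: dict) -> None:
    n = config.n_reports
    quarter, case_ids = ns["quarter"], ns["case_ids"]
    kept_id, dup_id, dup, dup_same_date, dup_lag = (
        ns["kept_id"], ns["dup_id"], ns["dup"], ns["dup_same_date"], ns["dup_lag"])
    receipt, start, onset = ns["receipt"], ns["start"], ns["onset"]
    start_prec, onset_prec = ns["start_prec"], ns["onset_prec"]
    sex, age, age_missing = ns["sex"], ns["age"], ns["age_missing"]
    weight, weight_missing = ns["weight"], ns["weight_missing"]
    country, occp, indication = ns["country"], ns["occp"], ns["indication"]
    outcome_flags = ns["outcome_flags"]
    outcome_codes = [o for o, _ in config.outcome_probs]
    ps_name, n_con, con_pool = ns["ps_name"], ns["n_con"], ns["con_pool"]
    events_by_report = ns["events_by_report"]
    deleted_mask = ns["deleted_mask"]
    bg_drugs = config.background_drugs()

    sex_out = np.where(sex == "UNK", "", sex)
    for q in config.quarters:
        members = sorted(np.flatnonzero(quarter == q))
        demo, drug_rows, reac, outc, indi = [], [], [], [], []
        for i in members:
            submissions = [(kept_id[i], receipt[i])]
            if dup[i]:
                d = receipt[i] if dup_same_date[i] else receipt[i] - _dt.timedelta(days=int(dup_lag[i]))
                submissions.insert(0, (dup_id[i], d))
            for rid, fda in submissions:
                demo.append([rid, case_ids[i], _fmt(fda),
                             sex_out[i],
                             "" if age_missing[i] else str(int(age[i])),
                             "" if age_missing[i] else "YR",
                             "" if weight_missing[i] else str(weight[i]),
                             "" if weight_missing[i] else "KG",
                             country[i], occp[i]])
                drug_rows.append([rid, "1", "PS", ps_name[i],
                                  _fmt(start[i], start_prec[i])])
                for k in range(int(n_con[i])):
                    drug_rows.append([rid, str(k + 2), "C",
                                      bg_drugs[int(con_pool[i, k])], ""])
                for pt in events_by_report.get(i, []):
                    reac.append([rid, pt, _fmt(onset[i], onset_prec[i])])
                for j, code in enumerate(outcome_codes):
                    if outcome_flags[i, j]:
                        outc.append([rid, code])
                indi.append([rid, "1", indication[i]])

        def dump(name: str, header: list[str], rows: list[list[str]]) -> None:
            lines = ["$".join(header)] + ["$".join(map(str, r)) for r in rows]
            (out / f"{name}{q}.txt").write_text("\n".join(lines) + "\n")

        dump("DEMO", ["primaryid", "caseid", "fda_dt", "sex", "age", "age_cod",
                      "wt", "wt_cod", "reporter_country", "occp_cod"], demo)
        dump("DRUG", ["primaryid", "drug_seq", "role_cod", "drugname", "start_dt"], drug_rows)
        dump("REAC", ["primaryid", "pt", "event_dt"], reac)
        dump("OUTC", ["primaryid", "outc_cod"], outc)
        dump("INDI", ["primaryid", "indi_drug_seq", "indi_pt"], indi)
        if q >= "2019Q1":
            listed = [case_ids[i] for i in members if deleted_mask[i]]
            (out / f"DELETED{q}.txt").write_text("\n".join(["caseid"] + listed) + "\n")


_JADER_ROLE_OUT = {"PS": "被疑薬", "C": "併用薬", "I": "相互作用"}
_JADER_SEX_OUT = {"F": "女性", "M": "男性", "UNK": "不明"}

# the target drug reported under its Japanese name in the JADER dialect
JADER_TARGET_NAME = "ガニレリクス酢酸塩"


def _write_jader(out: Path, config: GeneratorConfig, rng: np.random.Generator,
                 ns: dict) -> None:
    n = config.n_reports
    case_ids, receipt, start, onset = ns["case_ids"], ns["receipt"], ns["start"], ns["onset"]
    start_prec, onset_prec = ns["start_prec"], ns["onset_prec"]
    sex, age, age_missing = ns["sex"], ns["age"], ns["age_missing"]
    occp, indication, ps_cat = ns["occp"], ns["indication"], ns["ps_cat"]
    ps_name, n_con, con_pool = ns["ps_name"], ns["n_con"], ns["con_pool"]
    events_by_report = ns["events_by_report"]
    dup = ns["dup"]
    bg_drugs = config.background_drugs()

    def jdate(d: _dt.date, prec: str) -> str:
        if prec == "day":
            return f"{d.year:04d}/{d.month:02d}/{d.day:02d}"
        return f"{d.year:04d}/{d.month:02d}"

    demo, drug_rows, reac = [], [], []
    for i in range(n):
        name = JADER_TARGET_NAME if ps_cat[i] == "T" else ps_name[i]
        demo.append([case_ids[i], jdate(receipt[i], "day"), _JADER_SEX_OUT[sex[i]],
                     "" if age_missing[i] else f"{int(age[i]) // 10 * 10}歳代",
                     "医師" if occp[i] in ("MD", "PH") else "消費者", indication[i]])
        d_rows = [[case_ids[i], _JADER_ROLE_OUT["PS"], name,
                   jdate(start[i], start_prec[i])]]
        for k in range(int(n_con[i])):
            d_rows.append([case_ids[i], _JADER_ROLE_OUT["C"],
                           bg_drugs[int(con_pool[i, k])], ""])
        r_rows = [[case_ids[i], pt, jdate(onset[i], onset_prec[i])]
                  for pt in events_by_report.get(i, [])]
        if dup[i]:  # JADER duplication: exactly repeated table rows
            d_rows.append(list(d_rows[0]))
            if r_rows:
                r_rows.append(list(r_rows[0]))
        drug_rows.extend(d_rows)
        reac.extend(r_rows)

    def dump(name: str, header: list[str], rows: list[list[str]]) -> None:
        lines = [",".join(header)] + [",".join(map(str, r)) for r in rows]
        (out / f"{name}.csv").write_bytes(("\n".join(lines) + "\n").encode("cp932"))

    dump("demo", ["識別番号", "報告日", "性別", "年齢", "報告者職種", "原疾患"], demo)
    dump("drug", ["識別番号", "医薬品の関与", "医薬品（一般名）", "投与開始日"], drug_rows)
    dump("reac", ["識別番号", "有害事象", "有害事象の発現日"], reac)
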