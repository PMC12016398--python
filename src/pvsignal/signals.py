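"""Disproportionality statistics and consensus signal calls.

Four algorithms on each 2x2 table, with a drug-event pair flagged as a
positive signal only when all four clear their thresholds simultaneously:

* ROR  — reporting odds ratio ad/bc; positive when a >= 3 and the lower
  95% Wald limit exp(ln ROR - 1.96 SE) exceeds 1.
* PRR  — proportional reporting ratio [a/(a+b)]/[c/(c+d)] with the 2x2
  chi-square (no Yates correction); positive when a >= 3 and chi2 >= 4.
* BCPNN — information component IC = log2 of observed-over-expected
  reporting, with the Bayesian expectation E(IC) and variance V(IC) under
  Dirichlet priors; positive when IC025 = E(IC) - 2 sqrt(V(IC)) > 0.
* EBGM — the empirical Bayes geometric mean in its relative-reporting-ratio
  form a.N/((a+b)(a+c)); positive when the lower bound
  EBGM05 = exp(ln EBGM - 1.96 SE) exceeds 2.

Note the identity 2**IC == EBGM: the IC point estimate and the EBGM point
estimate are the same observed/expected ratio on two scales.

Zero cells: the default "haldane" policy adds 0.5 to every cell of a table
containing a zero for the ROR/EBGM point estimates and their shared
standard error (the Bayesian quantities already tolerate zeros through
their priors); policy "none" reports those statistics as NaN and the
corresponding flags stay False.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contingency import ContingencyTable, count_pairs, rollup_soc
from .model import CaseSet

__all__ = [
    "BCPNNPriors", "SignalStats", "SignalDecision", "Thresholds",
    "ror_stat", "prr_stat", "bcpnn_stat", "ebgm_stat", "decide", "detect",
    "compute_signal_frame", "se_ln_ratio",
]

_LN2_SQ = math.log(2.0) ** 2
_Z95 = 1.96

SIGNAL_COLUMNS = [
    "term", "level", "a", "b", "c", "d",
    "ror", "ror_low", "ror_high", "prr", "chi2",
    "ic", "ic025", "ebgm", "ebgm05",
    "ror_pos", "prr_pos", "bcpnn_pos", "mgps_pos", "consensus",
]


@dataclass(frozen=True)
class BCPNNPriors:
    """Dirichlet prior constants of the BCPNN information component.

    Defaults are the original BCPNN choice: symmetric cell priors
    alpha1 = beta1 = gamma11 = 1 with marginal strengths alpha = beta = 2;
    gamma is then derived from gamma11 and the margins so that the prior
    IC expectation is zero.
    """

    alpha: float = 2.0
    alpha1: float = 1.0
    beta: float = 2.0
    beta1: float = 1.0
    gamma11: float = 1.0

    def __post_init__(self) -> None:
        if min(self.alpha, self.alpha1, self.beta, self.beta1, self.gamma11) <= 0:
            raise ValueError("all BCPNN prior constants must be strictly positive")


@dataclass(frozen=True)
class Thresholds:
    """Signal thresholds: a >= 3, CI low > 1, chi2 >= 4, IC025 > 0, EBGM05 > 2."""

    min_a: int = 3
    ror_ci_low: float = 1.0
    chi2: float = 4.0
    ic025: float = 0.0
    ebgm05: float = 2.0
    prr_min: float | None = None  # optional PRR >= 2 gate, off by default


@dataclass
class SignalStats:
    ror: float
    ror_ci: tuple[float, float]
    se_ln_ror: float
    prr: float
    chi2: float
    ic: float
    e_ic: float
    v_ic: float
    ic025: float
    ebgm: float
    ebgm05: float
    a: int


@dataclass
class SignalDecision:
    ror_pos: bool
    prr_pos: bool
    bcpnn_pos: bool
    mgps_pos: bool
    triage: str = "none"

    @property
    def consensus(self) -> bool:
        return self.ror_pos and self.prr_pos and self.bcpnn_pos and self.mgps_pos


def se_ln_ratio(a, b, c, d):
    """Shared Wald standard error sqrt(1/a + 1/b + 1/c + 1/d)."""
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    return np.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)


def _corrected(a, b, c, d, zero_policy: str):
    """Cells used for ROR/EBGM/SE under the zero-cell policy."""
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    if zero_policy == "none":
        any_zero = (a == 0) | (b == 0) | (c == 0) | (d == 0)
        nan = np.where(any_zero, np.nan, 0.0)
        return a + nan, b + nan, c + nan, d + nan
    if zero_policy == "haldane":
        add = np.where((a == 0) | (b == 0) | (c == 0) | (d == 0), 0.5, 0.0)
        return a + add, b + add, c + add, d + add
    raise ValueError(f"unknown zero policy {zero_policy!r}")


def compute_signal_frame(tables: pd.DataFrame,
                         priors: BCPNNPriors = BCPNNPriors(),
                         zero_policy: str = "haldane",
                         thresholds: Thresholds = Thresholds()) -> pd.DataFrame:
    """Vectorised four-algorithm statistics for a frame of a,b,c,d cells."""
    out = tables.copy().reset_index(drop=True)
    a = out["a"].to_numpy(dtype=float)
    b = out["b"].to_numpy(dtype=float)
    c = out["c"].to_numpy(dtype=float)
    d = out["d"].to_numpy(dtype=float)
    n = a + b + c + d

    ac, bc_, cc, dc = _corrected(a, b, c, d, zero_policy)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = se_ln_ratio(ac, bc_, cc, dc)
        ror = (ac * dc) / (bc_ * cc)
        ror_low = np.exp(np.log(ror) - _Z95 * se)
        ror_high = np.exp(np.log(ror) + _Z95 * se)

        # PRR and chi-square on the raw cells (zero margins -> NaN, flag False)
        prr = (a / (a + b)) / (c / (c + d))
        chi2 = ((a * d - b * c) ** 2) * n / ((a + b) * (c + d) * (a + c) * (b + d))

        # observed/expected ratio: EBGM point estimate and IC = log2(EBGM)
        n_corr = ac + bc_ + cc + dc
        ebgm = (ac * n_corr) / ((ac + bc_) * (ac + cc))
        ic = np.log2((a * n) / ((a + b) * (a + c)))  # -inf when a = 0
        ebgm05 = np.exp(np.log(ebgm) - _Z95 * se)

        # BCPNN posterior moments under the Dirichlet priors
        p = priors
        gamma = p.gamma11 * (n + p.alpha) * (n + p.beta) / ((a + b + p.alpha1) * (a + c + p.beta1))
        e_ic = np.log2((a + p.gamma11) * (n + p.alpha) * (n + p.beta)
                       / ((n + gamma) * (a + b + p.alpha1) * (a + c + p.beta1)))
        v_ic = ((n - a + gamma - p.gamma11) / ((a + p.gamma11) * (1 + n + gamma))
                + (n - (a + b) + p.alpha - p.alpha1) / ((a + b + p.alpha1) * (1 + n + p.alpha))
                + (n - (a + c) + p.beta - p.beta1) / ((a + c + p.beta1) * (1 + n + p.beta))
                ) / _LN2_SQ
        ic025 = e_ic - 2.0 * np.sqrt(v_ic)

    t = thresholds
    with np.errstate(invalid="ignore"):
        ror_pos = (a >= t.min_a) & (ror_low > t.ror_ci_low)
        prr_pos = (a >= t.min_a) & (chi2 >= t.chi2)
        if t.prr_min is not None:
            prr_pos &= prr >= t.prr_min
        bcpnn_pos = ic025 > t.ic025
        mgps_pos = ebgm05 > t.ebgm05
    # NaN comparisons are already False; make that explicit for undefined stats
    ror_pos &= np.isfinite(ror_low)
    prr_pos &= np.isfinite(chi2) & np.isfinite(prr)
    mgps_pos &= np.isfinite(ebgm05)
    bcpnn_pos &= np.isfinite(ic025)

    out["ror"], out["ror_low"], out["ror_high"] = ror, ror_low, ror_high
    out["se_ln_ror"] = se
    out["prr"], out["chi2"] = prr, chi2
    out["ic"], out["e_ic"], out["v_ic"], out["ic025"] = ic, e_ic, v_ic, ic025
    out["ebgm"], out["ebgm05"] = ebgm, ebgm05
    out["ror_pos"], out["prr_pos"] = ror_pos, prr_pos
    out["bcpnn_pos"], out["mgps_pos"] = bcpnn_pos, mgps_pos
    out["consensus"] = ror_pos & prr_pos & bcpnn_pos & mgps_pos
    return out


def _frame_for(t: ContingencyTable) -> pd.DataFrame:
    return pd.DataFrame({"a": [t.a], "b": [t.b], "c": [t.c], "d": [t.d]})


def ror_stat(t: ContingencyTable, zero_policy: str = "haldane") -> tuple[float, float, tuple[float, float]]:
    """Reporting odds ratio with its Wald SE and 95% CI."""
    r = compute_signal_frame(_frame_for(t), zero_policy=zero_policy).iloc[0]
    return float(r["ror"]), float(r["se_ln_ror"]), (float(r["ror_low"]), float(r["ror_high"]))


def prr_stat(t: ContingencyTable) -> tuple[float, float]:
    """Proportional reporting ratio and its chi-square (no Yates correction)."""
    r = compute_signal_frame(_frame_for(t)).iloc[0]
    return float(r["prr"]), float(r["chi2"])


def bcpnn_stat(t: ContingencyTable, priors: BCPNNPriors = BCPNNPriors()) -> tuple[float, float, float, float]:
    """Information component: point IC, E(IC), V(IC), IC025 = E(IC) - 2 SD."""
    r = compute_signal_frame(_frame_for(t), priors=priors).iloc[0]
    return float(r["ic"]), float(r["e_ic"]), float(r["v_ic"]), float(r["ic025"])


def ebgm_stat(t: ContingencyTable, zero_policy: str = "haldane") -> tuple[float, float]:
    """Observed/expected reporting ratio (EBGM form) and its lower 95% bound."""
    r = compute_signal_frame(_frame_for(t), zero_policy=zero_policy).iloc[0]
    return float(r["ebgm"]), float(r["ebgm05"])


def stats_for(t: ContingencyTable, priors: BCPNNPriors = BCPNNPriors(),
              zero_policy: str = "haldane") -> SignalStats:
    r = compute_signal_frame(_frame_for(t), priors=priors, zero_policy=zero_policy).iloc[0]
    return SignalStats(
        ror=float(r["ror"]), ror_ci=(float(r["ror_low"]), float(r["ror_high"])),
        se_ln_ror=float(r["se_ln_ror"]), prr=float(r["prr"]), chi2=float(r["chi2"]),
        ic=float(r["ic"]), e_ic=float(r["e_ic"]), v_ic=float(r["v_ic"]),
        ic025=float(r["ic025"]), ebgm=float(r["ebgm"]), ebgm05=float(r["ebgm05"]),
        a=int(r["a"]),
    )


def decide(stats: SignalStats, thresholds: Thresholds = Thresholds()) -> SignalDecision:
    """Apply the four per-algorithm thresholds; undefined statistics fail."""
    t = thresholds

    def ok(x: float) -> bool:
        return x is not None and math.isfinite(x)

    ror_pos = stats.a >= t.min_a and ok(stats.ror_ci[0]) and stats.ror_ci[0] > t.ror_ci_low
    prr_pos = (stats.a >= t.min_a and ok(stats.chi2) and stats.chi2 >= t.chi2
               and (t.prr_min is None or (ok(stats.prr) and stats.prr >= t.prr_min)))
    bcpnn_pos = ok(stats.ic025) and stats.ic025 > t.ic025
    mgps_pos = ok(stats.ebgm05) and stats.ebgm05 > t.ebgm05
    return SignalDecision(ror_pos, prr_pos, bcpnn_pos, mgps_pos)


def detect(caseset: CaseSet, target_drug: list[str], level: str = "PT",
           role: str | None = "PS",
           priors: BCPNNPriors = BCPNNPriors(),
           zero_policy: str = "haldane",
           thresholds: Thresholds = Thresholds()) -> pd.DataFrame:
    """Full signal table for one drug: cells, statistics and decisions.

    One row per term at the requested level (``PT`` or ``SOC``), sorted by
    a descending; non-significant terms are retained with their flags
    False so the output doubles as the complete screening table.
    """
    if level.upper() == "PT":
        tables = count_pairs(caseset, target_drug, role)
    elif level.upper() == "SOC":
        tables = rollup_soc(caseset, target_drug, role)
    else:
        raise ValueError(f"level must be PT or SOC, got {level!r}")
    if tables.empty:
        return pd.DataFrame(columns=SIGNAL_COLUMNS)
    return compute_signal_frame(tables, priors=priors, zero_policy=zero_policy,
                                thresholds=thresholds)
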