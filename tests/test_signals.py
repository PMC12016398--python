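"""Four-algorithm disproportionality statistics and consensus calls.

Frozen expected values were computed by direct hand/numpy evaluation of
the 2x2 formulas (ad/bc, the proportion ratio, the chi-square identity and
log2 observed/expected) independently of the implementation.
"""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_caseset
from pvsignal.contingency import ContingencyTable
from pvsignal.signals import (BCPNNPriors, SignalStats, Thresholds, bcpnn_stat,
                              compute_signal_frame, decide, detect, ebgm_stat,
                              prr_stat, ror_stat, se_ln_ratio, stats_for)

T = ContingencyTable


class TestRor:
    def test_symmetric_table_is_null(self):
        ror, se, (lo, hi) = ror_stat(T(5, 5, 5, 5))
        assert ror == pytest.approx(1.0)
        assert lo < 1.0 < hi

    def test_frozen_example(self):
        # ad/bc = 10*9900/(90*100); se = sqrt(1/10+1/90+1/100+1/9900)
        ror, se, (lo, hi) = ror_stat(T(10, 90, 100, 9900))
        assert ror == pytest.approx(11.0, rel=1e-12)
        assert se == pytest.approx(math.sqrt(0.12121212121), rel=1e-9)
        assert lo == pytest.approx(11.0 * math.exp(-1.96 * se), rel=1e-12)
        assert lo == pytest.approx(5.5595, abs=1e-3)

    def test_wald_interval_reconstruction_large_background(self):
        # 1/c + 1/d -> 0: the interval depends on a and b alone
        se = se_ln_ratio(411, 2003, np.inf, np.inf)
        lo = 21.16 * math.exp(-1.96 * se)
        hi = 21.16 * math.exp(1.96 * se)
        assert round(lo, 2) == 19.03
        assert round(hi, 2) == 23.53

    def test_zero_cell_policy_none_flags_undefined(self):
        r = compute_signal_frame(pd.DataFrame({"a": [3], "b": [0], "c": [5], "d": [100]}),
                                 zero_policy="none").iloc[0]
        assert np.isnan(r["ror"]) and not r["ror_pos"]

    def test_zero_cell_haldane_computable(self):
        ror, se, _ = ror_stat(T(3, 0, 5, 100), zero_policy="haldane")
        assert np.isfinite(ror) and ror > 1


class TestPrr:
    def test_independence(self):
        prr, chi2 = prr_stat(T(5, 5, 5, 5))
        assert prr == pytest.approx(1.0) and chi2 == pytest.approx(0.0)

    def test_frozen_example(self):
        prr, chi2 = prr_stat(T(10, 90, 100, 9900))
        assert prr == pytest.approx(10.0, rel=1e-12)
        # (ad-bc)^2 N / [(a+b)(c+d)(a+c)(b+d)] evaluated by hand
        assert chi2 == pytest.approx(90000**2 * 10100 / (100 * 10000 * 110 * 9990),
                                     rel=1e-12)
        assert chi2 == pytest.approx(74.45, abs=0.01)

    def test_prr_approaches_ror_for_rare_events(self):
        # b >> a and d >> c: the odds ratio and proportion ratio converge
        t = T(6, 2408, 12, 88000)
        ror, _, _ = ror_stat(t)
        prr, _ = prr_stat(t)
        assert prr == pytest.approx(ror, rel=0.01)


class TestBcpnn:
    def test_exact_independence_gives_zero_ic(self):
        ic, e_ic, v_ic, ic025 = bcpnn_stat(T(1, 9, 9, 81))
        assert ic == pytest.approx(0.0, abs=1e-12)
        assert v_ic >= 0 and ic025 < 0

    def test_frozen_example(self):
        ic, *_ = bcpnn_stat(T(10, 90, 100, 9900))
        assert ic == pytest.approx(math.log2(101000 / 11000), rel=1e-12)
        assert ic == pytest.approx(3.199, abs=1e-3)

    def test_shrinkage_toward_null_for_sparse_table(self):
        ic, e_ic, v_ic, ic025 = bcpnn_stat(T(3, 0, 0, 997))
        assert e_ic < ic  # posterior expectation pulled toward 0
        assert ic025 == pytest.approx(e_ic - 2 * math.sqrt(v_ic), rel=1e-12)

    def test_e_ic_matches_direct_formula(self):
        # direct evaluation of the prior-augmented expectation, alpha1=beta1=gamma11=1, alpha=beta=2
        a, b, c, d = 7, 43, 120, 9830
        n = a + b + c + d
        gamma = (n + 2) * (n + 2) / ((a + b + 1) * (a + c + 1))
        expect = math.log2((a + 1) * (n + 2) * (n + 2)
                           / ((n + gamma) * (a + b + 1) * (a + c + 1)))
        _, e_ic, _, _ = bcpnn_stat(T(a, b, c, d))
        assert e_ic == pytest.approx(expect, rel=1e-12)

    def test_priors_must_be_positive(self):
        with pytest.raises(ValueError):
            BCPNNPriors(alpha=0)


class TestEbgm:
    def test_independence(self):
        ebgm, _ = ebgm_stat(T(1, 9, 9, 81))
        assert ebgm == pytest.approx(1.0)

    def test_frozen_example(self):
        ebgm, ebgm05 = ebgm_stat(T(10, 90, 100, 9900))
        assert ebgm == pytest.approx(101000 / 11000, rel=1e-12)
        se = se_ln_ratio(10, 90, 100, 9900)
        assert ebgm05 == pytest.approx(ebgm * math.exp(-1.96 * se), rel=1e-12)
        assert ebgm05 == pytest.approx(4.64, abs=0.01)

    @given(st.tuples(st.integers(1, 500), st.integers(1, 500),
                     st.integers(1, 500), st.integers(1, 5000)))
    @settings(deadline=None, max_examples=200)
    def test_identity_two_to_the_ic_equals_ebgm(self, cells):
        # IC and EBGM are the same observed/expected ratio on two scales
        r = compute_signal_frame(pd.DataFrame([dict(zip("abcd", cells))])).iloc[0]
        assert 2 ** r["ic"] == pytest.approx(r["ebgm"], rel=1e-9)


class TestMonotonicityAndCalibration:
    def test_increasing_a_increases_all_statistics(self):
        frames = compute_signal_frame(pd.DataFrame(
            {"a": [5, 10, 20], "b": [90] * 3, "c": [100] * 3, "d": [9900] * 3}))
        for col in ("ror", "prr", "ic", "ebgm"):
            assert frames[col].is_monotonic_increasing
            assert frames[col].nunique() == 3

    def test_proportional_margins_give_all_null(self):
        # a = (a+b)(a+c)/N exactly, margins proportional
        r = compute_signal_frame(pd.DataFrame({"a": [10], "b": [90], "c": [90], "d": [810]})).iloc[0]
        assert r["ror"] == pytest.approx(1.0)
        assert r["prr"] == pytest.approx(1.0)
        assert r["ic"] == pytest.approx(0.0, abs=1e-12)
        assert r["ebgm"] == pytest.approx(1.0)


def _stats(a=100, ci_low=2.0, chi2=50.0, ic025=1.0, ebgm05=5.0):
    return SignalStats(ror=3.0, ror_ci=(ci_low, 9.0), se_ln_ror=0.3, prr=3.0,
                       chi2=chi2, ic=2.0, e_ic=1.8, v_ic=0.1, ic025=ic025,
                       ebgm=4.0, ebgm05=ebgm05, a=a)


class TestDecide:
    def test_small_count_gate_blocks_huge_ror(self):
        d = decide(_stats(a=2, ci_low=50.0))
        assert not d.ror_pos and not d.prr_pos

    def test_boundaries_are_strict_or_inclusive_as_stated(self):
        assert not decide(_stats(ci_low=1.0)).ror_pos          # strict >
        assert decide(_stats(chi2=4.0)).prr_pos                # inclusive >=
        assert not decide(_stats(ic025=0.0)).bcpnn_pos         # strict >
        assert not decide(_stats(ebgm05=2.0)).mgps_pos         # strict >

    def test_consensus_requires_all_four(self):
        assert decide(_stats()).consensus
        assert not decide(_stats(ic025=-0.5)).consensus

    def test_undefined_statistic_fails_its_flag(self):
        assert not decide(_stats(ci_low=float("nan"))).ror_pos

    @given(st.integers(0, 10), st.floats(0.1, 10), st.floats(0, 100),
           st.floats(-5, 5), st.floats(0.1, 50))
    @settings(deadline=None, max_examples=100)
    def test_threshold_logic_is_pure(self, a, ci_low, chi2, ic025, ebgm05):
        s = _stats(a=a, ci_low=ci_low, chi2=chi2, ic025=ic025, ebgm05=ebgm05)
        d = decide(s)
        assert d.ror_pos == (a >= 3 and ci_low > 1)
        assert d.prr_pos == (a >= 3 and chi2 >= 4)
        assert d.bcpnn_pos == (ic025 > 0)
        assert d.mgps_pos == (ebgm05 > 2)
        assert d.consensus == (d.ror_pos and d.prr_pos and d.bcpnn_pos and d.mgps_pos)

    def test_optional_prr_gate(self):
        s = _stats()
        s.prr = 1.5
        assert not decide(s, Thresholds(prr_min=2.0)).prr_pos


class TestDetect:
    def test_empty_exposure_gives_empty_table(self):
        cs = make_caseset(reports=[("1", "1")], drugs=[("1", "OTHER", "PS")],
                          events=[("1", "X")])
        with pytest.warns(UserWarning):
            tab = detect(cs, ["GANIRELIX ACETATE"])
        assert tab.empty

    def test_rows_sorted_by_a_descending(self, faers_archive, small_config):
        path, _ = faers_archive
        from pvsignal.ingest import build_caseset, parse_faers_quarter
        from pvsignal.model import load_vocabulary
        cs = build_caseset([parse_faers_quarter(path, q) for q in small_config.quarters],
                           load_vocabulary(path / "vocabulary.tsv"))
        tab = detect(cs, list(small_config.target_synonyms))
        assert tab["a"].is_monotonic_decreasing
        assert {"term", "a", "ror", "ic025", "ebgm05", "consensus"} <= set(tab.columns)

    def test_unknown_level_rejected(self):
        cs = make_caseset(reports=[("1", "1")], drugs=[("1", "X", "PS")])
        with pytest.raises(ValueError, match="level"):
            detect(cs, ["X"], level="HLT")
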