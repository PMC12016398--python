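"""Time-to-onset intervals, Weibull failure typing, KM and log-rank."""
import numpy as np
import pytest

from conftest import make_caseset
from pvsignal.tto import (compute_tto, km_curves, logrank, one_per_report,
                          tto_bins, tto_describe, tto_table, weibull_fit)

TARGET = ["GANIRELIX ACETATE"]


def _cs(events, start="20200101"):
    """One exposed report per event tuple (pt, onset, [own start])."""
    reports, drugs, evs = [], [], []
    for i, e in enumerate(events):
        rid = str(i)
        pt, onset = e[0], e[1]
        st = e[2] if len(e) > 2 else start
        reports.append((rid, rid))
        drugs.append((rid, "GANIRELIX ACETATE", "PS", st))
        evs.append((rid, pt, onset))
    return make_caseset(reports=reports, drugs=drugs, events=evs,
                        vocabulary={"X": "S1", "Y": "S2"})


class TestComputeTto:
    def test_day_difference(self):
        rec, tally = compute_tto(_cs([("X", "20200115")]), TARGET)
        assert rec["days"].tolist() == [14]
        assert sum(tally.values()) == 0

    def test_onset_before_start_excluded_as_inconsistent(self):
        rec, tally = compute_tto(_cs([("X", "20200101", "20200115")]), TARGET)
        assert rec.empty and tally["inconsistent"] == 1

    def test_month_precision_onset_excluded_as_imprecise(self):
        rec, tally = compute_tto(_cs([("X", "202001")]), TARGET)
        assert rec.empty and tally["imprecise_onset"] == 1

    def test_missing_dates_tallied(self):
        rec, tally = compute_tto(_cs([("X", "")]), TARGET)
        assert tally["missing_onset"] == 1
        rec, tally = compute_tto(_cs([("X", "20200115", "")]), TARGET)
        assert tally["missing_start"] == 1
        rec, tally = compute_tto(_cs([("X", "20200115", "202001")]), TARGET)
        assert tally["imprecise_start"] == 1

    def test_same_day_event_is_zero_days(self):
        rec, _ = compute_tto(_cs([("X", "20200101")]), TARGET)
        assert rec["days"].tolist() == [0]

    def test_one_record_per_report_pt_and_earliest_per_report(self):
        cs = make_caseset(
            reports=[("1", "1")],
            drugs=[("1", "GANIRELIX ACETATE", "PS", "20200101")],
            events=[("1", "X", "20200110"), ("1", "X", "20200110"),
                    ("1", "Y", "20200105")])
        rec, _ = compute_tto(cs, TARGET)
        assert len(rec) == 2  # (report, PT) unit
        assert one_per_report(rec)["days"].tolist() == [4]


class TestBinsAndDescribe:
    def test_first_bin_closed_at_30(self):
        out = tto_bins([5, 29, 30])
        assert out.loc[0, "count"] == 3 and out.loc[0, "bin"] == "0-30"

    def test_paper_style_percentages(self):
        days = [10] * 186 + [45] * 32 + [70] * 32
        out = tto_bins(days)
        assert out.loc[0, "percent"] == 74.4
        assert out.loc[1, "percent"] == 12.8

    def test_percentages_sum_to_100(self):
        rng = np.random.default_rng(3)
        out = tto_bins(rng.integers(0, 400, size=251))
        assert out["percent"].sum() == pytest.approx(100.0, abs=0.1)

    def test_describe(self):
        d = tto_describe([1, 2, 3, 4, 5])
        assert (d["median"], d["q1"], d["q3"]) == (3, 2, 4)
        d = tto_describe([7])
        assert d["median"] == d["q1"] == d["q3"] == 7
        with pytest.raises(ValueError):
            tto_describe([])


class TestWeibullFit:
    @pytest.mark.parametrize("shape, expected", [(0.6, "early"), (1.0, "random"),
                                                 (2.0, "wear_out")])
    def test_failure_classification(self, shape, expected):
        rng = np.random.default_rng(11)
        x = 20.0 * rng.weibull(shape, size=500)
        fit = weibull_fit(x)
        assert fit.failure_type == expected
        assert fit.shape == pytest.approx(shape, rel=0.15)
        assert fit.shape_ci[0] <= fit.shape <= fit.shape_ci[1]

    def test_matches_lifelines_mle(self):
        from lifelines import WeibullFitter
        rng = np.random.default_rng(5)
        x = 15.0 * rng.weibull(1.4, size=300)
        fit = weibull_fit(x)
        wf = WeibullFitter().fit(x, event_observed=np.ones_like(x))
        assert fit.shape == pytest.approx(wf.rho_, rel=1e-3)
        assert fit.scale == pytest.approx(wf.lambda_, rel=1e-3)

    def test_zero_days_adjusted_and_counted(self):
        rng = np.random.default_rng(1)
        x = np.round(10 * rng.weibull(1.0, size=200))
        fit = weibull_fit(x)
        assert fit.n_zero_adjusted == int((x == 0).sum()) > 0

    def test_degenerate_and_tiny_samples_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            weibull_fit([5, 5, 5, 5])
        with pytest.raises(ValueError, match="at least 3"):
            weibull_fit([1, 2])

    def test_ci_coverage_and_median_recovery(self):
        # 100 replicates at n=250 per generating shape: CI covers the truth
        # ~95% of the time and the median estimate is close to the truth
        rng = np.random.default_rng(2024)
        for shape in (0.5, 1.0, 2.0):
            hits, estimates = 0, []
            for _ in range(100):
                fit = weibull_fit(20.0 * rng.weibull(shape, size=250))
                estimates.append(fit.shape)
                if fit.shape_ci[0] <= shape <= fit.shape_ci[1]:
                    hits += 1
            assert hits >= 90
            assert np.median(estimates) == pytest.approx(shape, rel=0.05)


class TestKmAndLogrank:
    def test_km_steps_of_one_third(self):
        out = km_curves({"g": [1, 2, 3]})
        inc = out.set_index("time")["cum_incidence"]
        assert inc.loc[1.0] == pytest.approx(1 / 3)
        assert inc.loc[2.0] == pytest.approx(2 / 3)
        assert inc.loc[3.0] == pytest.approx(1.0)

    def test_km_equals_empirical_cdf_without_censoring(self):
        rng = np.random.default_rng(8)
        days = rng.integers(0, 60, size=80)
        out = km_curves({"g": days})
        for t, ci in zip(out["time"], out["cum_incidence"]):
            assert ci == pytest.approx((days <= t).mean(), abs=1e-12)
        assert out["cum_incidence"].is_monotonic_increasing
        assert out["cum_incidence"].iloc[-1] == pytest.approx(1.0)

    def test_identical_groups_identical_curves_and_null_logrank(self):
        days = [3, 9, 27, 27, 50]
        out = km_curves({"g1": days, "g2": days})
        g1 = out[out.group == "g1"].drop(columns="group").reset_index(drop=True)
        g2 = out[out.group == "g2"].drop(columns="group").reset_index(drop=True)
        assert g1.equals(g2)
        stat, df, p = logrank({"g1": days, "g2": days})
        assert stat == pytest.approx(0.0, abs=1e-9)
        assert df == 1 and p == pytest.approx(1.0)

    def test_four_groups_three_degrees_of_freedom(self):
        rng = np.random.default_rng(9)
        groups = {f"g{i}": rng.weibull(1, 12) * 10 for i in range(4)}
        _, df, _ = logrank(groups)
        assert df == 3

    def test_separated_scales_strongly_significant(self):
        rng = np.random.default_rng(10)
        g = {"fast": 6.0 * rng.weibull(1.0, 19), "slow": 50.0 * rng.weibull(1.0, 17)}
        _, _, p = logrank(g)
        assert p < 0.001

    def test_empty_group_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="empty"):
            stat, df, p = logrank({"a": [1, 2], "b": [], "c": [2, 3]})
        assert df == 1


class TestTtoTable:
    def test_group_by_soc_respects_min_n(self):
        events = [("X", "202001%02d" % (i % 28 + 1)) for i in range(12)]
        events += [("Y", "20200105")] * 2
        rec, _ = compute_tto(_cs(events), TARGET)
        tab = tto_table(rec, group_by="soc", min_n=10)
        assert tab["group"].tolist() == ["S1"]
        tab_all = tto_table(rec, group_by="soc", min_n=1)
        assert set(tab_all["group"]) == {"S1", "S2"}
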