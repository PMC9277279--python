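"""Window construction, t-tests, linear models, nulls, pipeline."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from quakecall.detector import Detection
from quakecall.stats import (AnalysisConfig, DegenerateDifferencesError,
                             build_null_events, build_windows, binned_series,
                             fit_response_model, paired_t_test, rtm_slope,
                             run_full_analysis, simulate_window_counts,
                             tabulate_calls)
from quakecall.synth import ScenarioConfig, gen_scenario


class TestBuildWindows:
    def test_window_arithmetic(self):
        pairs = build_windows(10000.0, scales_h=[1], event_end_time=10060.0)
        p = pairs[0]
        assert p.before.as_tuple() == (6400.0, 10000.0)
        assert p.after.as_tuple() == (10060.0, 13660.0)

    def test_four_scales_four_pairs(self):
        pairs = build_windows(1e6, scales_h=[4, 3, 2, 1], event_end_time=1e6 + 30)
        assert len(pairs) == 4
        assert [p.scale_h for p in pairs] == [4, 3, 2, 1]

    def test_zero_duration_event(self):
        p = build_windows(500.0 * 3600, scales_h=[1])[0]
        assert p.after.start_s == 500.0 * 3600

    def test_truncation_flag(self):
        p = build_windows(1800.0, scales_h=[1], coverage=(0.0, 7200.0))[0]
        assert p.truncated  # before window would start at -1800 s

    def test_quake_interval_in_neither_window(self):
        p = build_windows(1000.0, scales_h=[1], event_end_time=1060.0)[0]
        assert p.before.end_s <= 1000.0 <= 1060.0 <= p.after.start_s


class TestBuildNullEvents:
    H = 3600.0

    def test_unobstructed_candidate_at_offset(self):
        nulls, failed = build_null_events([240.0 * self.H], [], offset_h=24.0)
        assert failed == []
        assert nulls == [240.0 * self.H - 24.0 * self.H]

    def test_one_null_per_earthquake(self):
        events = [100.0 * self.H, 300.0 * self.H, 500.0 * self.H]
        nulls, failed = build_null_events(events, events, offset_h=24.0, seed=3)
        assert len(nulls) == 3 and failed == []

    def test_shifts_clear_of_catalog(self):
        """A catalog event sitting right at the naive slot forces a shift;
        every returned null must end up >= 8 h from every catalog event."""
        ev = 400.0 * self.H
        catalog = [ev, ev - 24.0 * self.H, ev - 26.0 * self.H, ev - 30.0 * self.H]
        nulls, failed = build_null_events([ev], catalog, offset_h=24.0, seed=5)
        assert failed == []
        for t in nulls:
            assert all(abs(t - c) >= 8.0 * self.H for c in catalog)

    def test_no_room_reports_failure(self):
        ev = 5.0 * self.H  # candidate at -19 h: before the recording starts
        nulls, failed = build_null_events([ev], [], offset_h=24.0,
                                          coverage=(0.0, 40.0 * self.H),
                                          window_h=4.0)
        assert nulls == [] and failed == [ev]

    def test_deterministic(self):
        ev = 400.0 * self.H
        catalog = [ev, ev - 24.0 * self.H, ev - 27.0 * self.H]
        a, _ = build_null_events([ev], catalog, seed=11)
        b, _ = build_null_events([ev], catalog, seed=11)
        assert a == b


class TestPairedTTest:
    def test_identical_vectors(self):
        res = paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res == {"t": 0.0, "df": 2, "p": 1.0}

    def test_hand_computed_triple(self):
        """diffs [2, -1, 2]: mean 1, sd sqrt(3) -> t = 1.000, df = 2."""
        res = paired_t_test([10.0, 12.0, 8.0], [12.0, 11.0, 10.0])
        assert res["t"] == pytest.approx(1.000, abs=1e-9)
        assert res["df"] == 2

    def test_constant_nonzero_difference_is_degenerate(self):
        with pytest.raises(DegenerateDifferencesError):
            paired_t_test([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])

    def test_matches_scipy(self):
        rng = np.random.default_rng(8)
        b, a = rng.normal(size=(2, 40))
        res = paired_t_test(b, a)
        ref = sps.ttest_rel(a, b)
        assert res["t"] == pytest.approx(ref.statistic, rel=1e-12)
        assert res["p"] == pytest.approx(ref.pvalue, rel=1e-12)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            paired_t_test([1.0], [2.0])


def make_records(n, seed=0, stations=("A",)):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "event_id": [f"e{i}" for i in range(n)],
        "station_id": rng.choice(list(stations), size=n),
        "magnitude": rng.uniform(3.0, 4.5, n),
        "depth_km": rng.uniform(5.0, 60.0, n),
        "distance_km": rng.uniform(8.0, 342.0, n),
        "rl_dbfs_at_hydrophone": rng.uniform(-42.5, 0.0, n),
        "day_of_year": rng.integers(27, 181, n),
        "n_dcalls_before": rng.poisson(40.0, n).astype(float),
        "song_before": rng.uniform(0.5, 5.0, n),
    })
    df["delta_n_dcalls"] = rng.normal(size=n)
    df["delta_rl"] = rng.normal(size=n)
    df["delta_song"] = rng.normal(size=n)
    return df


class TestFitResponseModel:
    def test_exact_linear_response(self):
        rec = make_records(60, seed=1)
        rec["delta_n_dcalls"] = 2.0 * rec["magnitude"] - 5.0
        res = fit_response_model(rec, "delta_n_dcalls", "full")
        assert res.R_squared == pytest.approx(1.0, abs=1e-9)
        assert res.coefficients["magnitude"] == pytest.approx(2.0, abs=1e-8)

    def test_coefficients_match_normal_equations(self):
        """OLS estimates agree with a direct normal-equations solve."""
        rec = make_records(50, seed=4)
        res = fit_response_model(rec, "delta_song", "full")
        cols = ["depth_km", "magnitude", "distance_km", "rl_dbfs_at_hydrophone",
                "song_before", "day_of_year"]
        X = np.column_stack([np.ones(len(rec))] + [rec[c] for c in cols])
        y = rec["delta_song"].to_numpy()
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        fitted = res.coefficients[["Intercept"] + cols].to_numpy()
        np.testing.assert_allclose(fitted, beta, rtol=1e-8)

    def test_r_squared_matches_brute_force(self):
        rec = make_records(80, seed=6, stations=("A", "B"))
        res = fit_response_model(rec, "delta_n_dcalls", "context_only")
        # rebuild fitted values from the reported coefficients
        X = np.column_stack([
            np.ones(len(rec)),
            (rec.sort_values("station_id")["station_id"] == "B").astype(float),
            rec.sort_values("station_id")["n_dcalls_before"],
            rec.sort_values("station_id")["day_of_year"],
        ])
        order = ["Intercept", "C(station_id)[T.B]", "n_dcalls_before", "day_of_year"]
        y = rec.sort_values("station_id")["delta_n_dcalls"].to_numpy()
        resid = y - X @ res.coefficients[order].to_numpy()
        sse = np.sum(resid ** 2)
        sst = np.sum((y - y.mean()) ** 2)
        assert res.R_squared == pytest.approx(1.0 - sse / sst, rel=1e-9)

    def test_null_p_values_are_uniform(self):
        """With no true relationship the overall p-value is U(0,1) across
        replicate fits (Kolmogorov-Smirnov at alpha = 0.01)."""
        pvals = []
        for rep in range(200):
            rec = make_records(200, seed=10_000 + rep)
            res = fit_response_model(rec, "delta_n_dcalls", "context_only")
            assert res.R_squared < 0.15
            pvals.append(res.overall_p)
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_rank_deficiency_named(self):
        rec = make_records(50, seed=2)
        rec["distance_km"] = 2.0 * rec["magnitude"]
        with pytest.raises(ValueError, match="collinear"):
            fit_response_model(rec, "delta_n_dcalls", "full")

    def test_undefined_rows_dropped_with_warning(self):
        rec = make_records(40, seed=3)
        rec.loc[:4, "delta_rl"] = np.nan
        with pytest.warns(UserWarning, match="dropped 5"):
            res = fit_response_model(rec, "delta_rl", "context_only")
        assert res.n == 35

    def test_too_few_records_raises(self):
        with pytest.raises(ValueError, match="records than parameters"):
            fit_response_model(make_records(5, seed=1), "delta_n_dcalls", "full")


class TestBinnedSeries:
    def per_event(self, values_by_event):
        rows = []
        for eid, vals in values_by_event.items():
            for off, v in vals:
                rows.append({"event_id": eid, "bin_offset_min": off, "value": v})
        return pd.DataFrame(rows)

    def test_constant_metric(self):
        pe = self.per_event({"a": [(-15, 3.0), (0, 3.0)],
                             "b": [(-15, 3.0), (0, 3.0)]})
        out = binned_series(pe)
        assert (out["mean"] == 3.0).all()
        assert (out["standard_error"] == 0.0).all()
        assert (out["n_events"] == 2).all()

    def test_single_event_flagged(self):
        out = binned_series(self.per_event({"a": [(0, 5.0)]}))
        assert out.loc[0, "standard_error"] == 0.0
        assert out.loc[0, "n_events"] == 1

    def test_standard_error_formula(self):
        pe = self.per_event({"a": [(0, 1.0)], "b": [(0, 3.0)], "c": [(0, 5.0)]})
        out = binned_series(pe)
        assert out.loc[0, "mean"] == 3.0
        assert out.loc[0, "standard_error"] == pytest.approx(2.0 / np.sqrt(3))


class TestRegressionToTheMean:
    def test_iid_counts_slope_minus_one(self):
        """Independent before/after counts: the population slope of
        (after - before) on before is -1; the estimate's 95% CI covers it
        at n = 2000."""
        counts = simulate_window_counts(2000, 10.0, 10.0, 2.0, seed=314)
        res = rtm_slope(counts["before"], counts["after"])
        lo, hi = res["ci95"]
        assert lo <= -1.0 <= hi
        assert res["p_value"] < 1e-6  # the negative relationship is real

    def test_slope_equals_rho_minus_one(self):
        """With correlated before/after the slope converges to rho - 1."""
        rng = np.random.default_rng(9)
        rho = 0.5
        z = rng.normal(size=3000)
        before = z + rng.normal(scale=1.0, size=3000)
        after = rho * 2 * z / 2 + rng.normal(scale=np.sqrt(1 + rho), size=3000)
        # construct exactly: corr(before, after) = rho via shared component
        before = np.sqrt(rho) * z + np.sqrt(1 - rho) * rng.normal(size=3000)
        after = np.sqrt(rho) * z + np.sqrt(1 - rho) * rng.normal(size=3000)
        res = rtm_slope(before, after)
        assert res["slope"] == pytest.approx(rho - 1.0, abs=0.06)

    def test_earthquake_and_null_labels_indistinguishable(self):
        eq = simulate_window_counts(2000, 10.0, 10.0, 2.0, seed=1)
        null = simulate_window_counts(2000, 10.0, 10.0, 2.0, seed=2)
        r1, r2 = (rtm_slope(c["before"], c["after"]) for c in (eq, null))
        z = (r1["slope"] - r2["slope"]) / np.hypot(r1["stderr"], r2["stderr"])
        assert abs(z) < 3.0


class TestCalibration:
    def test_type_i_error_control(self):
        """No injected effect: the paired t-test rejects at alpha=0.05 in at
        most 10% of 50 seeded replicates (32 events each)."""
        rejections = 0
        for rep in range(50):
            counts = simulate_window_counts(32, 10.0, 10.0, 2.0, seed=2000 + rep)
            if paired_t_test(counts["before"], counts["after"])["p"] < 0.05:
                rejections += 1
        assert rejections <= 5

    def test_power_under_tripled_rate(self):
        """3x D-call rate after events: rejects in at least 90% of replicates."""
        rejections = 0
        for rep in range(50):
            counts = simulate_window_counts(32, 10.0, 30.0, 2.0, seed=4000 + rep)
            if paired_t_test(counts["before"], counts["after"])["p"] < 0.05:
                rejections += 1
        assert rejections >= 45


def _tiny_scenario():
    cfg = ScenarioConfig(duration_s=4800.0, dcall_rate_before=40.0,
                         dcall_rate_after=40.0, quake_times=[1400.0, 3400.0],
                         quake_duration_s=45.0, seed=19)
    return gen_scenario(cfg)


def _tiny_config(out_dir=None):
    return AnalysisConfig(scales_h=(0.1, 0.05), model_scale_h=0.1,
                          isolation_hours=0.2, null_offset_h=0.25,
                          span_h=0.05, bin_min=1.0, n_events=None,
                          seed=5, out_dir=out_dir)


class TestRunFullAnalysis:
    @pytest.fixture(scope="class")
    def tiny_run(self, tmp_path_factory):
        rec, truth, catalog, stations = _tiny_scenario()
        out = tmp_path_factory.mktemp("run1")
        res = run_full_analysis({"SYN1": rec}, catalog, stations,
                                _tiny_config(out))
        return res, out, catalog, stations, rec

    def test_pipeline_structure(self, tiny_run):
        res, out, catalog, *_ = tiny_run
        assert len(res.events) == 2
        # 2 events x 1 station x 2 kinds x 2 scales x 2 sides
        assert len(res.window_metrics) == 16
        assert not res.t_tests.empty
        assert (out / "run_log.json").exists()
        assert (out / "window_metrics.csv").exists()

    def test_quake_received_level_measured(self, tiny_run):
        res = tiny_run[0]
        assert res.events["rl_dbfs_at_hydrophone"].notna().all()
        np.testing.assert_allclose(res.events["event_time_s"], [1400.0, 3400.0])

    def test_null_windows_contain_no_catalog_event(self, tiny_run):
        res, _, catalog, stations, _ = tiny_run
        epoch = stations["deploy_start"].min()
        cat_s = [(t - epoch).total_seconds() for t in catalog["origin_time"]]
        for t_null in res.events["null_time_s"]:
            for s in (0.1, 0.05):
                lo, hi = t_null - s * 3600, t_null + s * 3600
                assert not any(lo <= c < hi for c in cat_s)

    def test_determinism(self, tiny_run, tmp_path):
        res1, out1, catalog, stations, rec = tiny_run
        out2 = tmp_path / "run2"
        run_full_analysis({"SYN1": rec}, catalog, stations, _tiny_config(out2))
        for name in ("events.csv", "window_metrics.csv", "t_tests.csv"):
            assert (out1 / name).read_bytes() == (out2 / name).read_bytes()


class TestScaleConsistency:
    def test_subwindowing_from_largest_scale_is_exact(self):
        """Counts and mean RL at the 1-h scale computed by sub-windowing the
        4-h extraction equal direct tabulation on the 1-h window."""
        rng = np.random.default_rng(44)
        t_ev = 5.0 * 3600
        dets = [Detection(start_s=s, end_s=s + 2.0, f_low_hz=30.0, f_high_hz=105.0,
                          score=0.9, best_template_id="t",
                          rl_dbfs=float(rng.uniform(-40, -10)), source="auto")
                for s in rng.uniform(t_ev - 4 * 3600, t_ev + 4 * 3600, 200)]
        pairs = build_windows(t_ev, scales_h=[4, 3, 2, 1])
        big = pairs[0]
        in_big = [d for d in dets
                  if big.before.start_s <= d.midpoint_s < big.after.end_s]
        for pair in pairs[1:]:
            for win in (pair.before, pair.after):
                direct = tabulate_calls(dets, win.as_tuple())
                subset = tabulate_calls(in_big, win.as_tuple())
                assert direct == subset
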