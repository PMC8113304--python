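"""Detection frequency, run extraction, peak timing, co-application."""

import math

import numpy as np
import pytest

from pollenhq import (
    PesticidePanel,
    PesticideProperty,
    SeriesSpec,
    SprayEventSpec,
    coapplication,
    detect_runs,
    detection_frequency,
    generate_series,
    peak_timing_summary,
    residues_per_day,
)

from conftest import make_series


@pytest.fixture
def one_analyte_panel():
    return PesticidePanel([
        PesticideProperty("x", "fungicide", loq=3, ld50_oral=10)])


def series_from_days(panel, detections):
    """{day: conc} for analyte 'x' over a contiguous 1..max(day) span."""
    n = max(detections)
    rows = {d: ({"x": detections[d]} if d in detections else {})
            for d in range(1, n + 1)}
    return make_series(rows, panel)


class TestDetectionFrequency:
    def test_counts_detection_days(self, small_series):
        d_f = detection_frequency(small_series)
        assert d_f["alpha"] == 4 and d_f["beta"] == 2

    def test_never_detected_is_zero(self, small_series):
        series = small_series.map_concentrations(
            lambda a, c: None if a == "gamma" else c)
        assert detection_frequency(series)["gamma"] == 0

    def test_matches_generator_truth(self):
        panel = PesticidePanel([
            PesticideProperty("x", "fungicide", loq=3, ld50_oral=10)])
        spec = SeriesSpec(
            n_days=30, panel=panel, noise_cv=0.0,
            events=[SprayEventSpec("x", 5, 200, rise_days=3, decay_days=6)])
        series, truth = generate_series(spec)
        assert (detection_frequency(series)["x"]
                == len(truth.expected_detection_days["x"]))


class TestResiduesPerDay:
    def test_median_over_days(self, small_panel):
        series = make_series({
            1: {}, 2: {"alpha": 5.0},
            3: {"alpha": 5.0, "beta": 5.0, "gamma": 6.0}}, small_panel)
        counts, summary = residues_per_day(series)
        assert counts.tolist() == [0, 1, 3]
        assert summary["median"] == 1
        assert summary["days_without_residues"] == 1

    def test_all_empty_series(self, small_panel):
        _, summary = residues_per_day(make_series({1: {}, 2: {}}, small_panel))
        assert summary["median"] == 0 and summary["max"] == 0


class TestDetectRuns:
    def test_contiguous_pulse_single_run(self, one_analyte_panel):
        # detections D7..D16, peak on D10
        conc = {d: 50.0 for d in range(7, 17)}
        conc[10] = 4530.0
        runs = detect_runs(series_from_days(one_analyte_panel, conc), "x")
        (run,) = runs
        assert (run.start_day, run.end_day) == (7, 16)
        assert run.peak_day == 10 and run.peak_conc == 4530.0
        assert run.days_to_peak == 4
        assert run.days_to_clearance == 6
        assert run.length_days == 10 and run.internal_gaps == 0

    def test_single_day_detection(self, one_analyte_panel):
        (run,) = detect_runs(series_from_days(one_analyte_panel, {4: 9.0}), "x")
        assert run.length_days == 1
        assert run.days_to_peak == 1 and run.days_to_clearance == 0

    @pytest.mark.parametrize("tolerance,n_runs,gaps", [(1, 1, 1), (0, 2, 0)])
    def test_embedded_nd_day_split_by_tolerance(
            self, one_analyte_panel, tolerance, n_runs, gaps):
        conc = {1: 10.0, 2: 20.0, 4: 15.0}  # ND on day 3
        runs = detect_runs(series_from_days(one_analyte_panel, conc), "x",
                           gap_tolerance=tolerance)
        assert len(runs) == n_runs
        assert sum(r.internal_gaps for r in runs) == gaps

    def test_missing_calendar_days_do_not_break_runs(self, one_analyte_panel):
        import datetime as dt
        from pollenhq import DailySample, ResidueSeries

        # day indices contiguous but a rain date sits between D2 and D3
        d0 = dt.date(2018, 4, 12)
        samples = [
            DailySample(1, d0, {"x": 5.0}),
            DailySample(2, d0 + dt.timedelta(days=1), {"x": 6.0}),
            DailySample(3, d0 + dt.timedelta(days=3), {"x": 7.0}),
        ]
        series = ResidueSeries(samples, one_analyte_panel,
                               missing_days={d0 + dt.timedelta(days=2)})
        runs = detect_runs(series, "x", gap_tolerance=0)
        assert len(runs) == 1 and runs[0].length_days == 3

    def test_runs_disjoint_ordered_and_monotone_in_tolerance(
            self, one_analyte_panel):
        rng = np.random.default_rng(42)
        for _ in range(20):
            days = {int(d): float(c) for d, c in zip(
                rng.choice(np.arange(1, 40), size=12, replace=False),
                rng.uniform(3, 100, size=12))}
            series = series_from_days(one_analyte_panel, days)
            prev_n = None
            for tol in (0, 1, 2, 5):
                runs = detect_runs(series, "x", gap_tolerance=tol)
                # disjoint and ordered
                for r1, r2 in zip(runs, runs[1:]):
                    assert r1.end_day < r2.start_day
                # peak is the max within the run (brute force)
                for r in runs:
                    inside = [c for d, c in days.items()
                              if r.start_day <= d <= r.end_day]
                    assert r.peak_conc == max(inside)
                    assert days[r.peak_day] == r.peak_conc
                # d_f conservation: detections = sum(length - gaps)
                assert sum(r.length_days - r.internal_gaps
                           for r in runs) == len(days)
                if prev_n is not None:
                    assert len(runs) <= prev_n
                prev_n = len(runs)


class TestPeakTimingSummary:
    def test_single_run(self, one_analyte_panel):
        runs = detect_runs(
            series_from_days(one_analyte_panel,
                             {1: 5.0, 2: 6.0, 3: 20.0, 4: 8.0}), "x")
        summary = peak_timing_summary(runs)
        assert summary["fraction_peak_within"] == 1.0

    def test_mixed_fraction(self):
        from pollenhq import DetectionRun

        runs = [
            DetectionRun("x", 1, 8, 8, 2, 9.0, 2, 6, 0),
            DetectionRun("x", 10, 20, 11, 16, 9.0, 7, 4, 0),
        ]
        assert peak_timing_summary(runs)["fraction_peak_within"] == 0.5

    def test_empty_input(self):
        assert peak_timing_summary([]) == {}

    def test_generator_fast_rises_peak_early(self):
        # events rising in <= 4 days peak within the first 5 days of
        # detection, so the early-peak fraction is 1 at zero noise
        panel = PesticidePanel([
            PesticideProperty(n, "fungicide", loq=3, ld50_oral=10)
            for n in ("x", "y", "z")])
        spec = SeriesSpec(n_days=60, panel=panel, noise_cv=0.0, events=[
            SprayEventSpec("x", 5, 400, rise_days=4, decay_days=6),
            SprayEventSpec("y", 20, 90, rise_days=1, decay_days=9),
            SprayEventSpec("z", 40, 1500, rise_days=3, decay_days=7)])
        series, _ = generate_series(spec)
        runs = []
        for name in panel.names:
            runs += detect_runs(series, name)
        summary = peak_timing_summary(runs)
        assert summary["n_runs"] == 3
        assert summary["fraction_peak_within"] == 1.0


class TestCoapplication:
    def test_exact_proportional_pair(self, small_panel):
        rows = {d: {"alpha": c, "beta": 2 * c}
                for d, c in enumerate([10.0, 40.0, 25.0, 90.0], start=1)}
        score = coapplication(make_series(rows, small_panel), "alpha", "beta")
        assert score.concentration_correlation == pytest.approx(1.0)
        assert score.ratio_cv == pytest.approx(0.0, abs=1e-12)
        assert score.shared_detection_days == 4

    def test_disjoint_detections_undefined(self, small_panel):
        rows = {1: {"alpha": 10.0}, 2: {"beta": 10.0}, 3: {"alpha": 5.0}}
        score = coapplication(make_series(rows, small_panel), "alpha", "beta")
        assert not score.defined
        assert score.shared_detection_days == 0

    def test_same_analyte_rejected(self, small_series):
        with pytest.raises(ValueError):
            coapplication(small_series, "alpha", "alpha")

    def test_noisy_one_to_one_pair_recovers_noise_level(self):
        """A 1:1 co-applied pair at 10% noise: ratio CV ~ sqrt(2)*0.1."""
        panel = PesticidePanel([
            PesticideProperty("a", "fungicide", loq=3, ld50_oral=100),
            PesticideProperty("b", "fungicide", loq=3, ld50_oral=50)])
        event = SprayEventSpec("a", 10, 2000, rise_days=3, decay_days=7,
                               co_applied=(("b", 1.0),))
        cvs, corrs = [], []
        for seed in range(30):
            spec = SeriesSpec(n_days=30, panel=panel, events=[event],
                              noise_cv=0.1, seed=seed)
            series, _ = generate_series(spec)
            score = coapplication(series, "a", "b")
            cvs.append(score.ratio_cv)
            corrs.append(score.concentration_correlation)
        assert np.mean(cvs) == pytest.approx(math.sqrt(2) * 0.1, rel=0.25)
        assert min(corrs) > 0.9
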