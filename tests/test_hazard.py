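"""Pollen hazard quotient scoring: PHQ, PHQmax, tPHQday, LD50 fractions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pollenhq import (
    HazardConfig,
    PesticidePanel,
    PesticideProperty,
    censor_below_loq,
    class_decomposition,
    classify_relevance,
    hazard_summary,
    ld50_fraction,
    phq,
    relevant_days,
    round_sigfigs,
)
from pollenhq.datasets import load_panel_table

from conftest import make_series


class TestPhq:
    def test_high_fungicide_peak_scores_55(self):
        # the season's highest concentration against a moderate LD50
        assert round_sigfigs(phq(4530, 83), 2) == 55

    def test_zero_concentration(self):
        assert phq(0, 5.0) == 0.0

    def test_absent_ld50_is_undefined_not_zero(self):
        assert phq(120, None) is None

    def test_nonpositive_ld50_rejected(self):
        with pytest.raises(ValueError):
            phq(10, 0.0)

    def test_linear_in_conc_inverse_in_ld50(self):
        assert phq(50, 10) == pytest.approx(5 * phq(10, 10))
        assert phq(50, 10) == pytest.approx(phq(50, 5) / 2)


class TestReportedPhqMaxReproduction:
    """PHQmax at 2 significant figures from the printed inputs."""

    REPRODUCIBLE = {
        "Tebuconazole": 55, "Fluopyram": 40, "Thiacloprid": 15,
        "Pendimethalin": 18, "Chlorantraniliprole": 3.0, "Acetamiprid": 2.1,
        "Boscalid": 1.2,
    }

    @pytest.mark.parametrize("analyte,expected", sorted(REPRODUCIBLE.items()))
    def test_phqmax_from_printed_inputs(self, study_table, analyte, expected):
        row = study_table.loc[analyte]
        value = round_sigfigs(phq(row.max_conc_ng_g, row.ld50_ug_bee), 2)
        assert value == pytest.approx(expected)
        assert value == pytest.approx(row.phq_max_reported)

    def test_kresoxim_methyl_agrees_at_printed_precision(self, study_table):
        # 10/110 = 0.0909 prints as 0.09 at two decimals (not 2 s.f.)
        row = study_table.loc["Kresoxim-methyl"]
        value = phq(row.max_conc_ng_g, row.ld50_ug_bee)
        assert abs(value - row.phq_max_reported) <= 0.005

    def test_methiocarb_known_discrepancy(self, study_table):
        # printed rounded inputs give exactly 175; the reported value is
        # 170; the mismatch stays within 5% (consistent with an
        # unrounded-input computation upstream)
        row = study_table.loc["Methiocarb"]
        value = phq(row.max_conc_ng_g, row.ld50_ug_bee)
        assert value == pytest.approx(175.0)
        assert abs(value - row.phq_max_reported) / row.phq_max_reported <= 0.05


class TestHazardSummary:
    def test_small_series_per_analyte(self, small_panel, small_series):
        table = hazard_summary(censor_below_loq(small_series))
        alpha = table.per_analyte.loc["alpha"]
        assert alpha.max_conc == 100.0
        assert alpha.phq_max == pytest.approx(1.0)
        assert alpha.mean_detected_conc == pytest.approx((10 + 100 + 30 + 6) / 4)
        assert alpha.detection_frequency == 4

    def test_single_detection_day_tphq(self, small_panel):
        series = make_series({1: {"alpha": 50.0}}, small_panel)
        table = hazard_summary(series)
        assert table.tphq.loc[1] == pytest.approx(phq(50.0, 100.0))

    def test_undefined_ld50_listed_and_excluded(self, small_panel, small_series):
        table = hazard_summary(censor_below_loq(small_series))
        assert table.undefined_analytes == {"delta"}
        # day 4: alpha 6 (LD50 100) detected alongside delta (no LD50)
        assert table.tphq.loc[4] == pytest.approx(0.06)

    def test_removing_undefined_analyte_preserves_tphq(
            self, small_panel, small_series):
        table = hazard_summary(censor_below_loq(small_series))
        dropped = small_series.map_concentrations(
            lambda a, c: None if a == "delta" else c)
        table2 = hazard_summary(censor_below_loq(dropped))
        assert np.allclose(table.tphq.values, table2.tphq.values)

    @given(st.data())
    @settings(max_examples=25, deadline=None)
    def test_tphq_matches_brute_force_sum(self, data):
        """tPHQday equals an independent per-day sum over conc/LD50."""
        n_analytes = data.draw(st.integers(2, 5))
        ld50s = [data.draw(st.one_of(
            st.none(), st.floats(0.05, 200, allow_nan=False)))
            for _ in range(n_analytes)]
        panel = PesticidePanel([
            PesticideProperty(f"a{i}", "fungicide", loq=1.0, ld50_oral=ld50s[i])
            for i in range(n_analytes)])
        n_days = data.draw(st.integers(1, 8))
        rows = {}
        for d in range(1, n_days + 1):
            rows[d] = {
                f"a{i}": data.draw(st.floats(1.0, 5000, allow_nan=False))
                for i in range(n_analytes)
                if data.draw(st.booleans())}
        series = make_series(rows, panel)
        table = hazard_summary(series)
        for d in range(1, n_days + 1):
            expected = sum(
                c / panel[a].ld50_oral
                for a, c in rows[d].items() if panel[a].ld50_oral is not None)
            assert table.tphq.loc[d] == pytest.approx(expected)
            contribs = table.contributions.loc[d].dropna()
            assert table.tphq.loc[d] == pytest.approx(contribs.sum())


class TestRelevance:
    @pytest.mark.parametrize("value,expected", [
        (50.0, False),   # strict rule: exactly at threshold is not relevant
        (50.001, True),
        (166, True),
        (0, False),
    ])
    def test_strict_threshold(self, value, expected):
        assert classify_relevance(value) is expected

    def test_inclusive_mode(self):
        cfg = HazardConfig(inclusive_threshold=True)
        assert classify_relevance(50.0, cfg) is True

    def test_relevant_days_match_classification(self, small_panel):
        series = make_series({1: {"beta": 30.0}, 2: {"beta": 20.0}},
                             small_panel)  # beta LD50 0.5 -> PHQ 60, 40
        table = hazard_summary(series)
        assert relevant_days(table) == [1]


class TestLd50Fraction:
    def test_reference_point(self):
        daily, period = ld50_fraction(100.0)
        assert round_sigfigs(daily, 1) == 0.1
        assert round_sigfigs(period, 1) == 1.0

    def test_zero(self):
        assert ld50_fraction(0.0) == (0.0, 0.0)

    def test_cumulative_four_day_window(self):
        # four consecutive high-load days (tPHQ 51+174+142+183 = 550):
        # over 500 tPHQ consumed, about 0.5% of the LD50 in the window
        total = sum([51, 174, 142, 183])
        daily, _ = ld50_fraction(total)
        assert total > 500
        assert round_sigfigs(daily, 1) == 0.5


class TestClassDecomposition:
    def test_single_class_day_is_full_share(self, small_panel):
        series = make_series({1: {"alpha": 50.0}}, small_panel)
        decomp = class_decomposition(hazard_summary(series))
        assert decomp.loc[1, "tphq_share_fungicide"] == pytest.approx(1.0)
        assert decomp.loc[1, "conc_share_fungicide"] == pytest.approx(1.0)

    def test_empty_day_totals_zero(self, small_panel):
        series = make_series({1: {}}, small_panel)
        decomp = class_decomposition(hazard_summary(series))
        assert decomp.loc[1, "tphq_total"] == 0.0
        assert decomp.loc[1, "conc_total"] == 0.0
        assert math.isnan(decomp.loc[1, "tphq_share_fungicide"])

    def test_insecticide_dominates_tphq_fungicide_dominates_conc(
            self, small_panel):
        # fungicide: high concentration, benign LD50; insecticide: low
        # concentration, tiny LD50 (the classic inversion)
        series = make_series({1: {"alpha": 1000.0, "beta": 10.0}}, small_panel)
        decomp = class_decomposition(hazard_summary(series))
        assert decomp.loc[1, "conc_share_fungicide"] > 0.9
        assert decomp.loc[1, "tphq_share_insecticide"] > 0.6
        shares = [decomp.loc[1, f"tphq_share_{c}"]
                  for c in ("fungicide", "herbicide", "insecticide")]
        assert sum(shares) == pytest.approx(1.0)

    def test_shares_sum_to_day_totals(self, small_panel, small_series):
        table = hazard_summary(censor_below_loq(small_series))
        decomp = class_decomposition(table)
        assert np.allclose(decomp["tphq_total"].values, table.tphq.values)


class TestRoundSigfigs:
    @pytest.mark.parametrize("x,n,expected", [
        (54.578, 2, 55), (39.7, 2, 40), (2.066, 2, 2.1), (0.0852, 1, 0.09),
        (175.2, 2, 180), (0, 2, 0),
    ])
    def test_values(self, x, n, expected):
        assert round_sigfigs(x, n) == pytest.approx(expected)
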