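"""Datasheet analytics: SF, dose response, Hill fits, ratios, qPCR."""

import json
import math

import numpy as np
import pandas as pd
import pytest

from bglbrick import synthdata as sd
from bglbrick.datasheet import (
    CopyNumberResult,
    StandardCurve,
    UndefinedRatioError,
    copy_number,
    copy_number_from_table,
    crosstalk_ratio,
    dose_response,
    fit_hill,
    fit_standard_curve,
    render_datasheet,
    repression_ratio,
    specific_fluorescence,
)


def _plate(noise=0.0, seed=1, doses=(0, 5, 10, 25, 50, 100, 250, 500), **kw):
    g = sd.GrowthModel()
    e = sd.ExpressionModel(noise_sd=noise, **kw)
    df, truth = sd.gen_plate(g, e, doses=list(doses), seed=seed)
    return specific_fluorescence(df), truth


class TestSpecificFluorescence:
    def test_pointwise_ratio(self):
        df = pd.DataFrame({"od600": [0.5], "fluor": [1000.0]})
        assert specific_fluorescence(df)["sf"].iloc[0] == 2000.0

    def test_gain_invariance(self):
        df = pd.DataFrame({"od600": [0.5, 0.8], "fluor": [1000.0, 1600.0]})
        doubled = df.assign(od600=df.od600 * 2, fluor=df.fluor * 2)
        assert np.allclose(
            specific_fluorescence(df)["sf"], specific_fluorescence(doubled)["sf"]
        )

    def test_low_od_masked_not_divided(self):
        df = pd.DataFrame({"od600": [0.01, 0.5], "fluor": [100.0, 100.0]})
        sf = specific_fluorescence(df)["sf"]
        assert np.isnan(sf.iloc[0]) and sf.iloc[1] == 200.0

    def test_all_masked_warns(self):
        df = pd.DataFrame({"od600": [0.01], "fluor": [1.0]})
        with pytest.warns(UserWarning, match="OD floor"):
            specific_fluorescence(df)


class TestDoseResponse:
    def test_control_normalizes_to_one(self):
        df, _ = _plate(noise=0.0)
        control = df["well"].str.startswith("control")
        # use the control wells also as the "sample" of interest
        summary = dose_response(df[control].copy(),
                                control_mask=control[control])
        # a single dose equal to the control: normalized value 1
        assert summary.normalized is None or np.allclose(summary.normalized, 1.0)

    def test_summary_uses_nearest_timepoint(self):
        df, _ = _plate(noise=0.0)
        summary = dose_response(df, control_mask=df.well.str.startswith("control"))
        assert abs(summary.actual_time_s - 18 * 3600) <= 570 / 2

    def test_monotone_doses_stay_monotone_after_normalization(self):
        df, _ = _plate(noise=0.0)
        summary = dose_response(df, control_mask=df.well.str.startswith("control"))
        assert list(summary.normalized) == sorted(summary.normalized)

    def test_noiseless_summary_matches_generator_truth(self):
        df, truth = _plate(noise=0.0)
        summary = dose_response(df, control_mask=df.well.str.startswith("control"))
        for c, m in zip(summary.doses, summary.mean_sf):
            assert m == pytest.approx(truth["sf_plateau_by_dose"][c], rel=1e-12)

    def test_missing_control_warns_but_reports_absolute(self):
        df, _ = _plate(noise=0.0)
        with pytest.warns(UserWarning, match="control"):
            summary = dose_response(df)
        assert summary.normalized is None and len(summary.doses) > 0


class TestFitHill:
    def test_flat_data_gives_zero_span(self):
        fit = fit_hill([0, 1, 10, 100], [5.0, 5.0, 5.0, 5.0])
        assert fit.span == pytest.approx(0.0, abs=1e-6)

    def test_noiseless_recovery_to_three_sig_figs(self):
        df, truth = _plate(noise=0.0, k_half=50.0, hill_n=2.0)
        summary = dose_response(df, control_mask=df.well.str.startswith("control"))
        fit = fit_hill(summary.doses, summary.mean_sf)
        assert fit.k_half == pytest.approx(50.0, rel=1e-3)
        assert fit.hill_n == pytest.approx(2.0, rel=1e-3)

    def test_k_recovery_under_five_percent_noise(self):
        ks = []
        for seed in range(30):
            df, _ = _plate(noise=0.05, seed=seed, k_half=50.0, hill_n=2.0)
            summary = dose_response(
                df, control_mask=df.well.str.startswith("control")
            )
            ks.append(fit_hill(summary.doses, summary.mean_sf).k_half)
        assert abs(np.mean(ks) - 50.0) / 50.0 < 0.20
        assert max(abs(k - 50.0) / 50.0 for k in ks) < 0.20

    def test_too_few_doses_rejected(self):
        with pytest.raises(ValueError):
            fit_hill([0, 1, 10], [1, 2, 3])


class TestRatios:
    def test_quoted_conventions(self):
        assert crosstalk_ratio(1.0, 1.4) == pytest.approx(40.0)
        assert repression_ratio(1.0, 0.8) == pytest.approx(-20.0)

    def test_identity_is_zero(self):
        assert crosstalk_ratio(3.7, 3.7) == 0.0
        assert repression_ratio(2.2, 2.2) == 0.0

    def test_nonpositive_baseline_undefined(self):
        with pytest.raises(UndefinedRatioError):
            crosstalk_ratio(0.0, 1.0)

    def test_planted_crosstalk_recovered(self):
        # +40% aTc crosstalk and 20% glucose repression planted in the generator
        base_df, _ = _plate(noise=0.0)
        up_df, _ = _plate(noise=0.0, crosstalk={"aTc": 0.4})
        control = base_df.well.str.startswith("control")
        s0 = dose_response(base_df, control_mask=control)
        up_df2, _ = sd.gen_plate(
            sd.GrowthModel(),
            sd.ExpressionModel(noise_sd=0.0, crosstalk={"aTc": 0.4}),
            doses=[0, 5, 10, 25, 50, 100, 250, 500], seed=1,
            noncognate=("aTc",),
        )
        s1 = dose_response(
            specific_fluorescence(up_df2),
            control_mask=up_df2.well.str.startswith("control"),
        )
        i = s0.doses.index(100.0)
        assert crosstalk_ratio(s0.mean_sf[i], s1.mean_sf[i]) == pytest.approx(40.0)

    def test_planted_repression_recovered(self):
        plain, _ = _plate(noise=0.0)
        glu_df, _ = sd.gen_plate(
            sd.GrowthModel(),
            sd.ExpressionModel(noise_sd=0.0, glucose_factor=0.8),
            doses=[0, 5, 10, 25, 50, 100, 250, 500], seed=1, glucose=True,
        )
        control = plain.well.str.startswith("control")
        s0 = dose_response(plain, control_mask=control)
        s1 = dose_response(
            specific_fluorescence(glu_df),
            control_mask=glu_df.well.str.startswith("control"),
        )
        i = s0.doses.index(100.0)
        assert repression_ratio(s0.mean_sf[i], s1.mean_sf[i]) == pytest.approx(-20.0)


class TestStandardCurve:
    def test_perfect_efficiency_closed_form(self):
        qs = [4.0 ** (-i) for i in range(7)]
        cts = [14 - math.log10(q) / math.log10(2.0) for q in qs]
        curve = fit_standard_curve(qs, cts)
        assert curve.slope == pytest.approx(-math.log2(10), abs=1e-12)
        assert curve.efficiency == pytest.approx(1.0, abs=1e-12)
        assert curve.r_squared == pytest.approx(1.0)

    def test_two_point_duplicates_give_exact_line(self):
        qs = [1.0, 1.0, 0.01, 0.01]
        cts = [10.0, 10.0, 16.0, 16.0]
        curve = fit_standard_curve(qs, cts)
        assert curve.slope == pytest.approx(-3.0)
        assert curve.intercept == pytest.approx(10.0)

    def test_slope_intercept_recovery_under_noise(self):
        slopes, intercepts = [], []
        model = sd.QpcrModel(ct_sd=0.1)
        expected = -1.0 / math.log10(1.0 + model.efficiency_nptii)
        for seed in range(100):
            df, _ = sd.gen_qpcr(model, seed=seed)
            std = df[(df.role == "standard") & (df.target == "nptII")]
            c = fit_standard_curve(std.dilution, std.ct)
            slopes.append(c.slope)
            intercepts.append(c.intercept)
        assert abs(np.mean(slopes) - expected) / abs(expected) < 0.02
        assert abs(np.mean(intercepts) - model.intercept_nptii) < 0.1

    def test_inverted_dilution_direction_rejected(self):
        with pytest.raises(ValueError, match="inverted"):
            fit_standard_curve([1, 0.1, 0.01], [10.0, 8.0, 6.0])

    def test_efficiency_invariant_under_unit_rescale(self):
        qs = np.array([4.0 ** (-i) for i in range(7)])
        cts = [20 - math.log10(q) / math.log10(1.9) for q in qs]
        c1 = fit_standard_curve(qs, cts)
        c2 = fit_standard_curve(qs * 123.0, cts)
        assert c1.slope == pytest.approx(c2.slope)
        assert c1.efficiency == pytest.approx(c2.efficiency)
        assert c1.intercept != pytest.approx(c2.intercept)


class TestCopyNumber:
    def _curves(self):
        qs = [4.0 ** (-i) for i in range(7)]
        cts = [14 - math.log10(q) / math.log10(2.0) for q in qs]
        curve = fit_standard_curve(qs, cts)
        return curve, curve

    def test_reference_maps_to_exactly_one(self):
        c1, c2 = self._curves()
        res = copy_number(20.0, 18.0, 20.0, 18.0, c1, c2)
        assert res.copy_number == 1.0

    def test_delta_ct_arithmetic(self):
        c1, c2 = self._curves()
        res = copy_number(20.0 - math.log2(10), 18.0, 20.0, 18.0, c1, c2)
        assert res.copy_number == pytest.approx(10.0)

    def test_extrapolation_warning_attached(self):
        c1, c2 = self._curves()
        res = copy_number(5.0, 18.0, 20.0, 18.0, c1, c2)
        assert any("outside calibrated range" in w for w in res.warnings)

    def test_planted_copy_number_recovered(self):
        vals = []
        for seed in range(40):
            df, _ = sd.gen_qpcr(sd.QpcrModel(copy_number=60, ct_sd=0.1), seed=seed)
            vals.append(copy_number_from_table(df).copy_number)
        assert abs(np.mean(vals) - 60) / 60 < 0.10


class TestRenderDatasheet:
    def test_json_round_trip_exact(self):
        df, _ = _plate(noise=0.0)
        summary = dose_response(df, control_mask=df.well.str.startswith("control"))
        fit = fit_hill(summary.doses, summary.mean_sf)
        doc, text = render_datasheet("pBbE5a-RFP", dose=summary, hill=fit)
        again = json.loads(json.dumps(doc))
        assert again == doc
        assert "pBbE5a-RFP" in text

    def test_empty_input_renders_metadata_only(self):
        doc, text = render_datasheet("pBbS2k-RFP")
        assert doc["dose_response"] is None
        assert text.count("not measured") >= 4

    def test_complete_panel_set(self):
        df, _ = _plate(noise=0.0)
        summary = dose_response(df, control_mask=df.well.str.startswith("control"))
        qdf, _ = sd.gen_qpcr(sd.QpcrModel(ct_sd=0.0), seed=1)
        doc, text = render_datasheet(
            "pBbE5a-RFP",
            dose=summary,
            hill=fit_hill(summary.doses, summary.mean_sf),
            media_panel={"LB": "strong", "M9": "weak"},
            crosstalk_panel={"aTc +400nM": 38.5},
            repression_panel={"LB +1% glucose": -20.0},
            copy=copy_number_from_table(qdf),
        )
        assert "not measured" not in text
        assert doc["copy_number"]["copy_number"] == pytest.approx(60.0)
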