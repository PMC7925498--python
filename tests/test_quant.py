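"""Calibration, LOD/LOQ, recovery, quantification and validation statistics."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sulfoquant import (
    CalibrationLevel,
    RecoveryInput,
    SingularFitError,
    composition_shares,
    cv_percent,
    fit_calibration,
    load_reference_shares,
    lod_loq,
    quantify,
    read_sample_sheet,
    recovery,
    validate_method,
)
from sulfoquant.simulate import simulate_calibration, simulate_validation_study

ISD_AREA = 1.0e5


def exact_levels(slope=0.330, intercept=0.018, concentrations=range(1, 11)):
    return [CalibrationLevel(float(c), (slope * c + intercept) * ISD_AREA, ISD_AREA)
            for c in concentrations]


class TestFitCalibration:
    def test_exact_line_recovered(self):
        curve = fit_calibration(exact_levels())
        assert curve.slope == pytest.approx(0.330, abs=1e-12)
        assert curve.intercept == pytest.approx(0.018, abs=1e-12)
        assert curve.r_squared == pytest.approx(1.0, abs=1e-12)
        assert curve.residual_sd == pytest.approx(0.0, abs=1e-10)
        assert curve.n_levels == 10

    def test_constant_response_is_singular(self):
        levels = [CalibrationLevel(float(c), 5e4, ISD_AREA) for c in range(1, 11)]
        with pytest.raises(SingularFitError):
            fit_calibration(levels)

    def test_identical_concentrations_are_singular(self):
        levels = [CalibrationLevel(5.0, a, ISD_AREA) for a in (1e4, 2e4, 3e4)]
        with pytest.raises(SingularFitError):
            fit_calibration(levels)

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError):
            fit_calibration(exact_levels(concentrations=[1, 2]))

    def test_noisy_slope_within_3_se_of_truth(self):
        levels, truth = simulate_calibration(noise_cv=0.01, seed=11)
        curve = fit_calibration(levels)
        assert abs(curve.slope - truth["response_factor"]) < 3 * curve.se_slope

    def test_weighted_fit_matches_on_noiseless_data(self):
        curve = fit_calibration(exact_levels(), weighting="1/x")
        assert curve.slope == pytest.approx(0.330, abs=1e-10)
        assert curve.weighting == "1/x"


class TestLodLoq:
    def test_zero_residual_gives_zero_limits(self):
        assert lod_loq(residual_sd=0.0, slope=0.33) == (0.0, 0.0)

    def test_closed_form(self):
        lod, loq = lod_loq(residual_sd=0.033, slope=0.330)
        assert loq == pytest.approx(1.0)
        assert lod == pytest.approx(0.33)

    def test_loq_lod_ratio_is_fixed(self):
        lod, loq = lod_loq(residual_sd=0.05, slope=0.4)
        assert loq / lod == pytest.approx(10 / 3.3)

    def test_nonpositive_slope_rejected(self):
        with pytest.raises(ValueError):
            lod_loq(residual_sd=0.1, slope=0.0)


class TestRecovery:
    @pytest.mark.parametrize("c_sample, c_endogen, c_spiked, expected", [
        (15.0, 5.0, 10.0, 100.0),
        (13.3, 5.0, 10.0, 83.0),
        (5.0, 5.0, 10.0, 0.0),
    ])
    def test_values(self, c_sample, c_endogen, c_spiked, expected):
        assert recovery(c_sample, c_endogen, c_spiked) == pytest.approx(expected)

    def test_zero_spike_rejected(self):
        with pytest.raises(ValueError):
            RecoveryInput(10.0, 5.0, 0.0)

    @given(a=st.floats(0.1, 100), b=st.floats(0.1, 100), c=st.floats(0.1, 100),
           k=st.floats(0.01, 1000))
    @settings(derandomize=True)
    def test_affine_invariance(self, a, b, c, k):
        assert recovery(k * a, k * b, k * c) == pytest.approx(recovery(a, b, c), rel=1e-9)


class TestCV:
    def test_known_value(self):
        assert cv_percent([1.0, 2.0, 3.0]) == pytest.approx(50.0)

    def test_constant_replicates(self):
        assert cv_percent([1.0] * 6) == 0.0

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError):
            cv_percent([1.0])

    @given(st.lists(st.floats(0.5, 100), min_size=2, max_size=20),
           st.floats(0.01, 1000))
    @settings(derandomize=True)
    def test_scale_invariance(self, values, k):
        assert cv_percent([k * v for v in values]) == pytest.approx(
            cv_percent(values), rel=1e-6, abs=1e-9)


class TestQuantify:
    def test_inverse_of_fit(self):
        curve = fit_calibration(exact_levels())
        response = curve.slope * 5.0 + curve.intercept
        report = quantify({"815": response * ISD_AREA}, curve, ISD_AREA)
        assert report.table.conc_ug_mL.iloc[0] == pytest.approx(5.0)

    def test_inverse_calibration_identity_on_levels(self):
        levels = exact_levels()
        curve = fit_calibration(levels)
        for lv in levels:
            report = quantify({"x": lv.analyte_area}, curve, lv.isd_area)
            assert report.table.conc_ug_mL.iloc[0] == pytest.approx(
                lv.nominal_concentration_ug_per_mL, abs=1e-9)

    def test_unit_arithmetic(self):
        # 5 ug/mL, 1 mL extract, 1:10 dilution, 0.5 g -> 0.1 mg/g
        curve = fit_calibration(exact_levels())
        response = curve.predict_response(5.0)
        report = quantify({"815": response * ISD_AREA}, curve, ISD_AREA,
                          dilution_factor=10.0, extract_volume_mL=1.0,
                          sample_mass_g=0.5)
        assert report.table.content_mg_g.iloc[0] == pytest.approx(0.1)

    def test_single_analyte_share_is_100(self):
        curve = fit_calibration(exact_levels())
        report = quantify({"815": curve.predict_response(5.0) * ISD_AREA},
                          curve, ISD_AREA)
        assert report.table.share_pct.iloc[0] == pytest.approx(100.0)

    def test_response_below_intercept_floored_and_flagged(self):
        curve = fit_calibration(exact_levels())
        report = quantify({"815": 0.0}, curve, ISD_AREA)
        row = report.table.iloc[0]
        assert row.conc_ug_mL == 0.0 and row.flag == "<LOD"

    def test_sub_loq_flagged_and_excluded_from_shares(self):
        levels, _ = simulate_calibration(noise_cv=0.02, seed=5)
        curve = fit_calibration(levels)
        assert curve.loq_ug_per_mL > 0
        hi = curve.predict_response(5.0) * ISD_AREA
        lo = curve.predict_response(curve.loq_ug_per_mL / 2) * ISD_AREA
        report = quantify({"815": hi, "817": lo}, curve, ISD_AREA)
        flags = dict(zip(report.table.analyte, report.table.flag))
        assert flags["817"] in ("<LOD", "<LOQ")
        shares = report.table.dropna(subset=["share_pct"])
        assert shares.share_pct.sum() == pytest.approx(100.0, abs=0.01)

    def test_invalid_inputs_rejected(self):
        curve = fit_calibration(exact_levels())
        with pytest.raises(ValueError):
            quantify({"815": 1.0}, curve, isd_area=0.0)
        with pytest.raises(ValueError):
            quantify({"815": 1.0}, curve, ISD_AREA, sample_mass_g=0.0)


class TestCompositionShares:
    def test_shares_sum_to_100(self):
        shares = composition_shares({"A": 2.0, "B": 1.0, "C": 1.0})
        assert shares == {"A": 50.0, "B": 25.0, "C": 25.0}
        assert sum(shares.values()) == pytest.approx(100.0, abs=0.01)

    def test_equal_contents(self):
        shares = composition_shares({k: 3.3 for k in "ABCD"})
        assert all(v == pytest.approx(25.0) for v in shares.values())

    def test_reference_shares_renormalize_to_100(self):
        published = load_reference_shares()
        renorm = composition_shares({k: v["mrm"] for k, v in published.items()})
        assert sum(renorm.values()) == pytest.approx(100.0, abs=1e-9)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            composition_shares({"A": 0.0, "B": 0.0})


class TestValidateMethod:
    def run_study(self, noise_cv=0.05, day_effect_cv=0.0, seed=4, **kwargs):
        calib, _ = simulate_calibration(noise_cv=0.005, seed=seed)
        qc, _ = simulate_validation_study(noise_cv=noise_cv,
                                          day_effect_cv=day_effect_cv,
                                          seed=seed, **kwargs)
        return validate_method([calib] * 3, qc)

    def test_constant_replicates_cv_zero_pass(self):
        calib = exact_levels()
        qc = pd.DataFrame([
            dict(nominal=5.0, day=1, replicate=r, response=0.33 * 5 + 0.018)
            for r in range(1, 7)
        ])
        report = validate_method([calib], qc)
        assert report.qc_table.intra_day_cv.iloc[0] == pytest.approx(0.0, abs=1e-9)
        assert report.passes

    def test_fail_flag_above_threshold(self):
        calib = exact_levels()
        # responses engineered to a back-calculated CV of ~16%
        concs = np.array([5.0, 5.8, 4.2, 6.0, 4.0, 5.0])
        qc = pd.DataFrame([
            dict(nominal=5.0, day=1, replicate=i + 1, response=0.33 * c + 0.018)
            for i, c in enumerate(concs)
        ])
        report = validate_method([calib], qc, cv_threshold=15.0)
        assert report.qc_table.intra_day_cv.iloc[0] > 15.0
        assert not report.passes

    def test_simulated_study_meets_fda_bound(self):
        report = self.run_study(noise_cv=0.05)
        assert report.passes
        assert (report.qc_table.intra_day_cv < 15.0).all()
        assert report.qc_table.accuracy_pct.between(90, 110).all()

    def test_day_effect_raises_inter_day_cv(self):
        report = self.run_study(noise_cv=0.01, day_effect_cv=0.1, seed=8)
        assert (report.qc_table.inter_day_cv > report.qc_table.intra_day_cv).all()

    def test_single_replicate_rejected(self):
        calib = exact_levels()
        qc = pd.DataFrame([dict(nominal=5.0, day=1, replicate=1, response=1.668)])
        with pytest.raises(ValueError):
            validate_method([calib], qc)


class TestRoundTripStudy:
    def test_back_calculation_within_5pct_at_1pct_noise(self):
        # full simulated study: calibration + unknowns at known concentrations
        levels, truth = simulate_calibration(noise_cv=0.01, seed=21)
        curve = fit_calibration(levels)
        rng = np.random.default_rng(22)
        rf = truth["response_factor"]
        for true_conc in (2.0, 5.0, 9.0):
            response = rf * true_conc * (1 + rng.normal(0, 0.01))
            if true_conc >= curve.loq_ug_per_mL:
                report = quantify({"a": response * ISD_AREA}, curve, ISD_AREA)
                assert report.table.conc_ug_mL.iloc[0] == pytest.approx(
                    true_conc, rel=0.05)


def test_sample_sheet_round_trip(tmp_path):
    sheet = pd.DataFrame([
        dict(sample_id="cal1", type="calibrant", nominal_conc_ug_mL=1.0, day=1,
             replicate=1, dilution_factor=1.0, extract_volume_mL=1.0, sample_mass_g=1.0),
        dict(sample_id="spir1", type="sample", nominal_conc_ug_mL=np.nan, day=1,
             replicate=1, dilution_factor=100.0, extract_volume_mL=1.0, sample_mass_g=0.5),
    ])
    path = tmp_path / "samples.csv"
    sheet.to_csv(path, index=False)
    loaded = read_sample_sheet(path)
    assert list(loaded.sample_id) == ["cal1", "spir1"]
    bad = tmp_path / "bad.csv"
    sheet.assign(type="mystery").to_csv(bad, index=False)
    with pytest.raises(ValueError):
        read_sample_sheet(bad)
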