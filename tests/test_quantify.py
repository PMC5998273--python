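"""Calibration fitting/inversion, control gating, aggregation, dilution and
the assembled card-analysis pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from saltcard import simulate
from saltcard.imaging import ZoneSignal
from saltcard.quantify import (
    CalibrationCurve,
    CalibrationError,
    ControlLimits,
    ZoneReading,
    aggregate_concentration,
    analyze_card,
    default_control_spec,
    dilution_factor,
    fit_zone_calibration,
    invert_calibration,
    load_calibration,
    save_calibration,
    validate_controls,
)
from saltcard.simulate import ZoneChemistry, identity_scenario, render_card, zone_response


def _sig(zone_id, value, unreadable=False):
    return ZoneSignal(zone_id, float(value), 100, 0.0, unreadable=unreadable)


class TestFitCalibration:
    def test_exact_standards_recover_line(self):
        chem = ZoneChemistry(threshold=0.0, gain=2.0, background_signal=5.0, saturation_signal=105.0)
        pts = [(c, zone_response(c, chem)) for c in [5.0, 10.0, 20.0, 30.0, 40.0]]
        curve = fit_zone_calibration(1, pts)
        assert curve.slope == pytest.approx(2.0, abs=1e-9)
        assert curve.intercept == pytest.approx(5.0, abs=1e-9)
        lo, hi = curve.signal_range
        assert lo == pytest.approx(15.0, abs=1e-9)
        assert hi == pytest.approx(85.0, abs=1e-9)

    def test_all_saturated_errors(self):
        chem = ZoneChemistry(threshold=0.0, gain=10.0, background_signal=5.0, saturation_signal=105.0)
        pts = [(c, zone_response(c, chem)) for c in [20.0, 30.0, 40.0, 50.0]]
        with pytest.raises(CalibrationError, match="usable"):
            fit_zone_calibration(2, pts)

    def test_plateaus_excluded_from_fit(self):
        chem = ZoneChemistry(threshold=10.0, gain=5.0, background_signal=20.0, saturation_signal=120.0)
        concs = [0, 2, 4, 6, 8, 10, 12, 14, 16, 18, 20, 25, 30, 35, 40, 45]
        pts = [(c, zone_response(c, chem)) for c in concs]
        curve = fit_zone_calibration(3, pts)
        # plateau points would drag the slope down; exclusion recovers it
        assert curve.slope == pytest.approx(chem.gain, abs=1e-9)
        assert curve.intercept == pytest.approx(
            chem.background_signal - chem.gain * chem.threshold, abs=1e-6
        )

    def test_noisy_standards_slope_within_three_se(self):
        rng = np.random.default_rng(7)
        gain, icpt, sd, n = 2.0, 5.0, 1.0, 6
        ppm = np.linspace(5, 45, n)
        sig = icpt + gain * ppm + rng.normal(0, sd, n)
        curve = fit_zone_calibration(4, list(zip(ppm, sig)))
        se = sd / np.sqrt(((ppm - ppm.mean()) ** 2).sum())
        assert curve.slope == pytest.approx(gain, abs=3 * se)

    def test_too_few_points_errors(self):
        with pytest.raises(CalibrationError):
            fit_zone_calibration(5, [(0.0, 10.0), (10.0, 50.0)])

    def test_round_trip_file(self, tmp_path):
        curves = {
            1: CalibrationCurve(1, 2.0, 5.0, (10.0, 90.0), source="test"),
            2: CalibrationCurve(2, 3.5, -1.0, (20.0, 150.0), source="test"),
        }
        path = tmp_path / "curves.yaml"
        save_calibration(curves, path)
        again = load_calibration(path)
        assert again == curves


class TestInvertCalibration:
    CURVE = CalibrationCurve(1, 2.0, 5.0, (10.0, 90.0))

    def test_exact_inverse(self):
        reading = invert_calibration(_sig(1, 5.0 + 2.0 * 20.0), self.CURVE)
        assert reading.status == "in_range"
        assert reading.concentration == pytest.approx(20.0, abs=1e-12)

    def test_above_range_no_concentration(self):
        reading = invert_calibration(_sig(1, 95.0), self.CURVE)
        assert reading.status == "out_of_range"
        assert reading.concentration is None

    def test_signal_at_intercept_is_zero_ppm(self):
        curve = CalibrationCurve(1, 2.0, 15.0, (10.0, 90.0))
        reading = invert_calibration(_sig(1, 15.0), curve)
        assert reading.concentration == pytest.approx(0.0, abs=1e-12)

    def test_unreadable_passes_through(self):
        reading = invert_calibration(_sig(1, 50.0, unreadable=True), self.CURVE)
        assert reading.status == "unreadable"

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        slope=st.floats(0.1, 20),
        intercept=st.floats(-50, 50),
        c=st.floats(0, 50),
    )
    def test_inversion_is_exact_over_linear_range(self, slope, intercept, c):
        curve = CalibrationCurve(9, slope, intercept, (0.0, 255.0))
        s = intercept + slope * c
        if 0.0 <= s <= 255.0:
            reading = invert_calibration(_sig(9, s), curve)
            assert reading.concentration == pytest.approx(c, abs=1e-9 * max(1.0, c))


class TestControls:
    def _spec(self, layout):
        return default_control_spec(layout)

    def test_nominal_controls_pass(self, layout):
        spec = self._spec(layout)
        sigs = [
            _sig(z.id, 45.0 if z.role == "negative_control" else 175.0)
            for z in layout.control_zones
        ]
        ok, details = validate_controls(sigs, layout, spec)
        assert ok

    def test_developed_negative_fails_naming_zone(self, layout):
        spec = self._spec(layout)
        neg = next(z for z in layout.control_zones if z.role == "negative_control")
        sigs = [
            _sig(z.id, 175.0) for z in layout.control_zones  # negative too dark
        ]
        ok, details = validate_controls(sigs, layout, spec)
        assert not ok
        assert any(f"zone {neg.id}" in d and "above maximum" in d for d in details)

    def test_inactive_positive_fails(self, layout):
        spec = self._spec(layout)
        sigs = [_sig(z.id, 45.0) for z in layout.control_zones]  # positive at background
        ok, details = validate_controls(sigs, layout, spec)
        assert not ok

    def test_unreadable_control_fails(self, layout):
        spec = self._spec(layout)
        sigs = [
            _sig(z.id, 45.0 if z.role == "negative_control" else 175.0,
                 unreadable=(z.role == "positive_control"))
            for z in layout.control_zones
        ]
        ok, details = validate_controls(sigs, layout, spec)
        assert not ok
        assert any("unreadable" in d for d in details)


class TestAggregate:
    def _reading(self, c, status="in_range", role="measurement"):
        return ZoneReading(
            _sig(1, 50.0), status, c if status == "in_range" else None, role=role
        )

    def test_identical_replicates(self):
        est, disp, n = aggregate_concentration([self._reading(12.0)] * 3)
        assert (est, disp, n) == (12.0, 0.0, 3)

    def test_median_of_three(self):
        est, _, _ = aggregate_concentration(
            [self._reading(c) for c in (10.0, 12.0, 17.0)]
        )
        assert est == 12.0

    def test_out_of_range_excluded(self):
        readings = [self._reading(c) for c in (10.0, 11.0, 12.0)] + [
            self._reading(None, status="out_of_range") for _ in range(9)
        ]
        est, _, n = aggregate_concentration(readings)
        assert n == 3
        assert est == 11.0

    def test_even_count_mean_of_middle_pair(self):
        est, _, _ = aggregate_concentration(
            [self._reading(c) for c in (10.0, 12.0, 14.0, 20.0)]
        )
        assert est == 13.0

    def test_no_in_range_raises(self):
        with pytest.raises(ValueError):
            aggregate_concentration([self._reading(None, status="out_of_range")])


class TestDilution:
    def test_equal_mass_unit_density(self):
        assert dilution_factor(1.0, 1.0, 1.0) == pytest.approx(2.0, abs=1e-12)

    def test_stated_sample_prep_is_one_to_five(self):
        # 3.25 g salt in 15.00 g water with brine density ~1.123 g/mL
        assert dilution_factor(3.25, 15.00, 1.123) == pytest.approx(5.00, abs=0.01)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        salt=st.floats(0.5, 10),
        water=st.floats(1, 100),
        density=st.floats(0.9, 1.3),
        ppm=st.floats(0, 100),
    )
    def test_mass_balance_round_trip(self, salt, water, density, ppm):
        # solution mg/L implied by the solid ppm, mapped back through the factor
        solution = ppm * salt * density / (salt + water)
        factor = dilution_factor(salt, water, density)
        assert factor * solution == pytest.approx(ppm, rel=1e-9, abs=1e-9)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            dilution_factor(0.0, 15.0, 1.1)


class TestAnalyzeCard:
    def test_noiseless_card_recovered(self, layout, chems, curves):
        img, _ = render_card(layout, chems, identity_scenario(20.0))
        res = analyze_card(img, layout, curves)
        assert res.accepted
        assert res.concentration_estimate == pytest.approx(20.0, abs=1.0)
        assert res.n_used >= 3
        assert len(res.readings) == 12
        assert res.survey_class == "adequate"

    def test_failed_negative_control_rejected(self, layout, chems, curves):
        neg = next(z for z in layout.zones if z.role == "negative_control")
        img, _ = render_card(
            layout, chems, identity_scenario(20.0),
            zone_concentration_override={neg.id: 40.0},
        )
        res = analyze_card(img, layout, curves)
        assert res.verdict == "rejected"
        assert res.rejection_reason == "controls_failed"

    def test_dead_positive_control_rejected(self, layout, chems, curves):
        pos = next(z for z in layout.zones if z.role == "positive_control")
        img, _ = render_card(
            layout, chems, identity_scenario(20.0),
            zone_concentration_override={pos.id: 0.0},
        )
        res = analyze_card(img, layout, curves)
        assert res.rejection_reason == "controls_failed"

    def test_three_occluded_fiducials_rejected(self, layout, chems, curves):
        img, truth = render_card(layout, chems, identity_scenario(20.0))
        img = img.copy()
        for f in layout.fiducials[:3]:
            x, y = truth.fiducial_centers_px[f.id]
            r = int(f.radius * 10) + 5
            img[int(y) - r : int(y) + r, int(x) - r : int(x) + r] = 255
        res = analyze_card(img, layout, curves)
        assert res.rejection_reason == "too_few_fiducials"

    def test_above_range_card_rejected_no_in_range(self, layout, chems, curves):
        img, _ = render_card(layout, chems, identity_scenario(80.0))
        res = analyze_card(img, layout, curves)
        assert res.rejection_reason == "no_in_range_zones"

    def test_estimate_monotone_in_concentration(self, layout, chems, curves):
        estimates = []
        for c in np.arange(2.0, 35.0, 4.0):
            img, _ = render_card(layout, chems, identity_scenario(float(c)))
            res = analyze_card(img, layout, curves)
            assert res.accepted
            estimates.append(res.concentration_estimate)
        diffs = np.diff(estimates)
        assert (diffs > -0.05).all()
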