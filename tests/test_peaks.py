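"""Trace I/O, peak detection, integration, and retention-time assignment."""

import io
import math

import numpy as np
import pytest

from sulfoquant import (
    Peak,
    Role,
    Trace,
    assign_peaks,
    detect_peaks,
    integrate,
    read_traces,
    resolve_channels,
    write_traces_csv,
    write_traces_mzml,
)
from sulfoquant.peaks import TraceError, srm_channel_id


def gaussian_trace(apex=20.5, sigma=0.1, amplitude=1e5, t0=0.0, t1=52.0, dt=0.01,
                   baseline=0.0, channel="chan"):
    t = np.arange(t0, t1 + dt / 2, dt)
    y = amplitude * np.exp(-0.5 * ((t - apex) / sigma) ** 2) + baseline
    return Trace(channel_id=channel, time_min=t, intensity=y)


class TestTrace:
    def test_non_monotone_time_rejected(self):
        with pytest.raises(TraceError):
            Trace("x", np.array([0.0, 1.0, 1.0]), np.array([0.0, 1.0, 0.0]))

    def test_negative_intensity_rejected(self):
        with pytest.raises(TraceError):
            Trace("x", np.array([0.0, 1.0]), np.array([0.0, -1.0]))

    def test_srm_id_parsing(self):
        tr = Trace(srm_channel_id(815.4, 80.9), np.array([0.0, 1.0]), np.array([0.0, 0.0]))
        assert tr.srm_q1q3 == (815.4, 80.9)


class TestReadWrite:
    def test_csv_round_trip(self, tmp_path):
        traces = [gaussian_trace(channel=srm_channel_id(815.4, 80.9)),
                  gaussian_trace(apex=10.0, channel=srm_channel_id(555.0, 80.0)),
                  gaussian_trace(apex=30.0, channel=srm_channel_id(792.0, 96.0))]
        path = tmp_path / "traces.csv"
        write_traces_csv(traces, path)
        back = read_traces(path)
        assert len(back) == 3
        for a, b in zip(traces, back):
            assert a.channel_id == b.channel_id
            np.testing.assert_allclose(a.time_min, b.time_min)
            np.testing.assert_allclose(a.intensity, b.intensity)

    def test_mzml_round_trip(self, tmp_path):
        traces = [gaussian_trace(channel=srm_channel_id(815.4, 80.9)),
                  gaussian_trace(apex=12.5, channel=srm_channel_id(792.0, 96.0))]
        path = tmp_path / "traces.mzML"
        write_traces_mzml(traces, path)
        back = read_traces(path)
        assert [t.channel_id for t in back] == [t.channel_id for t in traces]
        for a, b in zip(traces, back):
            np.testing.assert_allclose(a.time_min, b.time_min, atol=1e-9)
            np.testing.assert_allclose(a.intensity, b.intensity)

    def test_empty_file_rejected(self, tmp_path):
        empty = tmp_path / "empty.csv"
        empty.write_text("")
        with pytest.raises(TraceError):
            read_traces(empty)

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(TraceError):
            read_traces(tmp_path / "x.raw")

    def test_channel_resolution(self, panel):
        traces = [gaussian_trace(channel=srm_channel_id(815.4, 80.9)),
                  gaussian_trace(channel=srm_channel_id(400.0, 80.0))]
        resolved = resolve_channels(traces, panel)
        assert (resolved[0].analyte, resolved[0].role) == ("815", Role.QUANTIFIER)
        assert resolved[1].analyte is None


class TestDetectPeaks:
    def test_single_gaussian_apex(self):
        peaks = detect_peaks(gaussian_trace(apex=20.5, sigma=0.1, amplitude=1e5))
        assert len(peaks) == 1
        assert peaks[0].apex_rt_min == pytest.approx(20.5, abs=0.02)

    def test_flat_zero_trace(self):
        t = np.arange(0, 52, 0.01)
        assert detect_peaks(Trace("flat", t, np.zeros_like(t))) == []

    def test_two_gaussians_two_minutes_apart(self):
        t = np.arange(0, 52, 0.01)
        y = (1e5 * np.exp(-0.5 * ((t - 20.0) / 0.1) ** 2)
             + 5e4 * np.exp(-0.5 * ((t - 22.0) / 0.1) ** 2))
        peaks = detect_peaks(Trace("two", t, y))
        assert len(peaks) == 2
        assert [round(p.apex_rt_min, 1) for p in peaks] == [20.0, 22.0]

    def test_detected_area_matches_closed_form(self):
        amplitude, sigma = 1e5, 0.1
        peaks = detect_peaks(gaussian_trace(amplitude=amplitude, sigma=sigma))
        expected = amplitude * sigma * math.sqrt(2 * math.pi)
        assert peaks[0].area_counts == pytest.approx(expected, rel=0.01)

    def test_noisy_snr_filter(self):
        rng = np.random.default_rng(7)
        t = np.arange(0, 52, 0.01)
        noise = np.abs(rng.normal(0, 50.0, t.size))
        y = 1e5 * np.exp(-0.5 * ((t - 20.5) / 0.1) ** 2) + noise
        peaks = detect_peaks(Trace("noisy", t, y), min_snr=5.0)
        assert len(peaks) == 1
        assert peaks[0].snr > 5.0

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            detect_peaks(Trace("tiny", np.array([0.0, 1.0]), np.array([0.0, 0.0])))


class TestIntegrate:
    def test_gaussian_closed_form(self):
        amplitude, sigma = 1e5, 0.1
        tr = gaussian_trace(apex=20.5, sigma=sigma, amplitude=amplitude)
        area = integrate(tr, 20.5 - 5 * sigma, 20.5 + 5 * sigma)
        assert area == pytest.approx(amplitude * sigma * math.sqrt(2 * math.pi), rel=0.01)

    def test_zero_trace(self):
        t = np.arange(0, 10, 0.01)
        assert integrate(Trace("z", t, np.zeros_like(t)), 1.0, 9.0) == 0.0

    def test_rectangle_exact(self):
        t = np.arange(0, 10.001, 0.5)
        h = 123.0
        area = integrate(Trace("r", t, np.full_like(t, h)), 2.0, 6.0)
        assert area == pytest.approx(h * 4.0, abs=1e-9)

    def test_bounds_outside_span_rejected(self):
        tr = gaussian_trace()
        with pytest.raises(ValueError):
            integrate(tr, -1.0, 5.0)
        with pytest.raises(ValueError):
            integrate(tr, 5.0, 5.0)

    def test_area_invariant_under_time_shift_and_linear_in_intensity(self):
        tr = gaussian_trace(apex=20.5)
        area = integrate(tr, 19.5, 21.5)
        shifted = Trace(tr.channel_id, tr.time_min + 7.0, tr.intensity)
        assert integrate(shifted, 26.5, 28.5) == pytest.approx(area, rel=1e-12)
        scaled = Trace(tr.channel_id, tr.time_min, tr.intensity * 3.5)
        assert integrate(scaled, 19.5, 21.5) == pytest.approx(3.5 * area, rel=1e-12)


class TestAssignPeaks:
    def make_peak(self, apex, area=1000.0):
        return Peak(apex_rt_min=apex, left_rt_min=apex - 0.3, right_rt_min=apex + 0.3,
                    area_counts=area, height_counts=area, snr=100.0)

    def test_isd_peak_assigned(self, panel):
        table = assign_peaks({("792", Role.QUANTIFIER): [self.make_peak(20.5)]}, panel, 0.5)
        row = table.iloc[0]
        assert bool(row.assigned) and row.analyte == "792"

    def test_far_peak_unassigned(self, panel):
        table = assign_peaks({("792", Role.QUANTIFIER): [self.make_peak(25.0)]}, panel, 0.5)
        assert not table.assigned.any()
        assert (table.note == "outside_window").all()

    def test_missing_panel_rt_flagged(self, panel):
        table = assign_peaks({("867", Role.QUANTIFIER): [self.make_peak(15.0)]}, panel, 0.5)
        assert list(table.note) == ["no_panel_rt"]
        assert not table.assigned.any()

    def test_two_peaks_in_window_largest_wins(self, panel):
        peaks = [self.make_peak(20.4, area=500.0), self.make_peak(20.6, area=900.0)]
        table = assign_peaks({("792", Role.QUANTIFIER): peaks}, panel, 0.5)
        winner = table[table.assigned]
        assert len(winner) == 1
        assert winner.iloc[0].area == 900.0
        assert winner.iloc[0].note == "multiple_in_window"

    def test_tolerance_must_be_positive(self, panel):
        with pytest.raises(ValueError):
            assign_peaks({}, panel, 0.0)
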