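import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pulsewave.waveform_analysis import (
    PressureWaveform,
    augmentation_index,
    calibrate_waveform,
    detect_landmarks,
    foot_time,
    pulse_wave_velocity,
    sevr,
    waveform_indices,
)


def two_gaussian_wave(fs=256.0, T=1000.0, foot=80.0, peak=180.0,
                      shoulder=260.0, notch=360.0):
    """Synthetic radial-like beat with construction-known landmarks."""
    t = np.arange(0.0, T, 1000.0 / fs)
    p = 78.0 + 1.5 * np.exp(-((t - foot - 250) / 260.0) ** 2)
    p = p + 38.0 * np.exp(-((t - peak) / 55.0) ** 2)
    p = p + 14.0 * np.exp(-((t - shoulder) / 70.0) ** 2)
    # dicrotic notch: sharp dip (staying above end-diastole) + secondary wave
    p = p - 2.5 * np.exp(-((t - notch) / 16.0) ** 2)
    p = p + 4.0 * np.exp(-((t - notch - 55) / 45.0) ** 2)
    return PressureWaveform(time_ms=t, pressure=p, calibrated=True)


class TestCalibration:
    def test_affine_map_to_brachial_range(self):
        t = np.arange(0, 1000, 10.0)
        w = PressureWaveform(time_ms=t, pressure=np.sin(t / 100.0) * 0.5 + 0.5)
        c = calibrate_waveform(w, 120.0, 80.0)
        assert c.pressure.min() == pytest.approx(80.0, abs=1e-12)
        assert c.pressure.max() == pytest.approx(120.0, abs=1e-12)
        assert c.calibrated

    def test_identity_when_already_spanning(self):
        t = np.arange(0, 1000, 10.0)
        p = 80 + 40 * (np.sin(t / 159.0) * 0.5 + 0.5)
        pmax, pmin = p.max(), p.min()
        w = PressureWaveform(time_ms=t, pressure=p)
        c = calibrate_waveform(w, pmax, pmin)
        assert np.allclose(c.pressure, p, atol=1e-10)

    def test_idempotent(self):
        t = np.arange(0, 1000, 10.0)
        w = PressureWaveform(time_ms=t, pressure=np.cos(t / 70.0))
        once = calibrate_waveform(w, 125.0, 82.0)
        twice = calibrate_waveform(once, 125.0, 82.0)
        assert np.allclose(once.pressure, twice.pressure, atol=1e-12)

    def test_flat_waveform_rejected(self):
        t = np.arange(0, 1000, 10.0)
        w = PressureWaveform(time_ms=t, pressure=np.full_like(t, 90.0))
        with pytest.raises(ValueError):
            calibrate_waveform(w, 120, 80)

    def test_nonuniform_sampling_rejected(self):
        t = np.arange(0, 1000, 10.0).astype(float)
        t[17] += 3.0
        with pytest.raises(ValueError):
            PressureWaveform(time_ms=t, pressure=np.sin(t))


class TestAugmentationIndex:
    @pytest.mark.parametrize("sp,dp,ap,expected", [
        (120.0, 80.0, 0.0, 100.0),
        (120.0, 80.0, 10.0, 400.0 / 3.0),
        (120.0, 80.0, 20.0, 200.0),
    ])
    def test_printed_formula(self, sp, dp, ap, expected):
        assert augmentation_index(sp, dp, ap) == pytest.approx(expected)

    def test_ap_at_pulse_pressure_rejected(self):
        with pytest.raises(ValueError):
            augmentation_index(120, 80, 40)

    @given(dp=st.floats(40, 100), pp=st.floats(20, 80),
           ap_frac=st.floats(-0.5, 0.9),
           scale=st.floats(0.5, 2.0), offset=st.floats(-20, 20))
    @settings(max_examples=200, deadline=None)
    def test_invariant_under_affine_recalibration(self, dp, pp, ap_frac,
                                                  scale, offset):
        sp, ap = dp + pp, ap_frac * pp
        ai1 = augmentation_index(sp, dp, ap)
        ai2 = augmentation_index(scale * sp + offset, scale * dp + offset,
                                 scale * ap)
        assert ai1 == pytest.approx(ai2, rel=1e-9)


class TestSEVR:
    def test_constant_pressure_equal_halves(self):
        t = np.arange(0, 1000, 5.0)
        w = PressureWaveform(time_ms=t, pressure=np.full_like(t, 100.0))
        assert sevr(w, 500.0) == pytest.approx(100.0)

    def test_constant_pressure_interval_ratio(self):
        t = np.arange(0, 1000, 5.0)
        w = PressureWaveform(time_ms=t, pressure=np.full_like(t, 100.0))
        assert sevr(w, 300.0) == pytest.approx((1000 - 300) / 300 * 100)

    def test_vanishing_diastole(self):
        t = np.arange(0, 1000, 5.0)
        w = PressureWaveform(time_ms=t, pressure=np.full_like(t, 100.0))
        assert sevr(w, 995.0) < 1.0

    def test_monotone_decreasing_in_ed(self):
        t = np.arange(0, 1000, 5.0)
        p = 90 + 30 * np.exp(-((t - 250) / 140) ** 2)
        w = PressureWaveform(time_ms=t, pressure=p)
        values = [sevr(w, ed) for ed in (250.0, 350.0, 450.0)]
        assert values[0] > values[1] > values[2]

    def test_ed_outside_cycle_rejected(self):
        t = np.arange(0, 1000, 5.0)
        w = PressureWaveform(time_ms=t, pressure=np.full_like(t, 100.0))
        with pytest.raises(ValueError):
            sevr(w, 1500.0)


class TestLandmarks:
    def test_two_gaussian_construction(self):
        w = two_gaussian_wave()
        lm = detect_landmarks(w)
        dt = w.dt_ms
        assert lm.systolic_peak % w.period_ms == pytest.approx(182.0, abs=3 * dt)
        assert lm.notch % w.period_ms == pytest.approx(360.0, abs=4 * dt)
        assert lm.notch_detected

    def test_half_sine_notch(self):
        T, fs, ED = 1000.0, 128.0, 330.0
        t = np.arange(0, T, 1000 / fs)
        sys = 78 + 42 * np.sin(np.pi * t / ED)
        dia = (78 + 42 * np.sin(np.pi * 0.999)) * np.exp(-(t - ED) / 900.0)
        dia = 78 * np.exp(-(t - ED) / 1400.0)
        p = np.where(t <= ED, sys, dia)
        w = PressureWaveform(time_ms=t, pressure=p)
        lm = detect_landmarks(w)
        ed_est = (lm.notch - lm.foot) % w.period_ms
        assert ed_est == pytest.approx(ED, abs=2.5 * w.dt_ms)

    def test_monotone_ramp_fallback(self):
        t = np.arange(0, 1000, 10.0)
        w = PressureWaveform(time_ms=t, pressure=80 + 0.04 * t)
        lm = detect_landmarks(w)
        assert not lm.notch_detected  # fallback ED estimate flagged

    def test_waveform_indices_consistency(self):
        w = two_gaussian_wave()
        idx = waveform_indices(w)
        assert idx.PP == pytest.approx(idx.SP - idx.DP)
        assert idx.SP == pytest.approx(w.pressure.max())
        assert idx.DP == pytest.approx(w.pressure.min())
        assert idx.AI == pytest.approx(
            idx.PP / (idx.PP - idx.AP) * 100.0, rel=1e-9)
        assert 0 < idx.ED < w.period_ms


class TestPWV:
    def test_same_site_rejected(self, hd_mean_sim):
        with pytest.raises(ValueError):
            pulse_wave_velocity(hd_mean_sim, "femoral", "femoral")

    def test_headline_path_magnitude(self, hd_mean_sim):
        # aortic arch to femoral at the printed HD cohort-mean stiffness:
        # the study-scale values are 7.7-10 m/s
        v = pulse_wave_velocity(hd_mean_sim, "aortic_arch", "femoral")
        assert 6.0 < v < 14.0

    def test_foot_time_on_known_shift(self):
        t = np.arange(0, 1000, 2.0)
        base = 80 + 35 / (1 + np.exp(-(t - 200) / 18.0)) * np.exp(-t / 900)
        w1 = PressureWaveform(time_ms=t, pressure=base)
        shifted = np.interp((t - 60) % 1000.0, t, base)
        w2 = PressureWaveform(time_ms=t, pressure=shifted)
        d = (foot_time(w2) - foot_time(w1)) % 1000.0
        assert d == pytest.approx(60.0, abs=4.0)
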