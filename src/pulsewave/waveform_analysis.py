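"""Pulse wave analysis: calibration, landmarks, AI, SEVR, and model PWV.

Implements the standard tonometry-style indices on a single-cycle pressure
waveform: systolic/diastolic pressure, augmented pressure AP (pressure added
by the reflected wave, measured between the systolic shoulder and the peak),
the augmentation index AI = (SP-DP)/(SP-DP-AP) x 100%, ejection duration ED
(pulse foot to dicrotic notch), and the sub-endocardial viability ratio
SEVR = diastolic / systolic pressure-time integral x 100%.  Pulse wave
velocity between two sites of a simulated tree is measured foot-to-foot with
the intersecting-tangent method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import savgol_filter

from .arterial_tree import path_length
from .hemodynamics import SimulationResult

__all__ = [
    "PressureWaveform",
    "PWAIndices",
    "Landmarks",
    "calibrate_waveform",
    "detect_landmarks",
    "augmentation_index",
    "sevr",
    "waveform_indices",
    "foot_time",
    "pulse_wave_velocity",
]


@dataclass(frozen=True)
class PressureWaveform:
    """One cardiac cycle of uniformly sampled pressure.

    ``time_ms`` starts at 0 and covers one period within one sample;
    ``pressure`` in mmHg (or arbitrary units before calibration).
    """

    time_ms: np.ndarray
    pressure: np.ndarray
    calibrated: bool = False
    HR: float | None = None  # beats/min, when known

    def __post_init__(self):
        t = np.asarray(self.time_ms, dtype=float)
        p = np.asarray(self.pressure, dtype=float)
        if t.ndim != 1 or t.shape != p.shape or t.size < 8:
            raise ValueError("waveform needs matching 1D arrays (>= 8 samples)")
        dt = np.diff(t)
        if np.any(dt <= 0) or (np.max(dt) - np.min(dt)) > 1e-6 * np.mean(dt) + 1e-9:
            raise ValueError("waveform must be uniformly sampled in time")
        if not np.all(np.isfinite(p)):
            raise ValueError("pressures must be finite")
        object.__setattr__(self, "time_ms", t)
        object.__setattr__(self, "pressure", p)

    @property
    def dt_ms(self) -> float:
        return float(self.time_ms[1] - self.time_ms[0])

    @property
    def sampling_rate(self) -> float:
        """Hz"""
        return 1000.0 / self.dt_ms

    @property
    def period_ms(self) -> float:
        return float(self.time_ms[-1] - self.time_ms[0] + self.dt_ms)


@dataclass(frozen=True)
class Landmarks:
    """Characteristic times (ms, on the waveform's clock)."""

    foot: float
    systolic_peak: float
    shoulder: float
    notch: float
    notch_detected: bool = True
    waveform_type: str = "A"  # "A": shoulder precedes peak (late systolic peak)


@dataclass(frozen=True)
class PWAIndices:
    SP: float  # mmHg
    DP: float
    PP: float
    AP: float
    AI: float  # percent
    ED: float  # ms
    SEVR: float  # percent
    waveform_type: str = "A"
    notch_detected: bool = True


def calibrate_waveform(
    w: PressureWaveform, brachial_SP: float, brachial_DP: float
) -> PressureWaveform:
    """Affinely rescale so the waveform spans [brachial_DP, brachial_SP] mmHg."""
    if not brachial_SP > brachial_DP > 0:
        raise ValueError("require brachial_SP > brachial_DP > 0")
    p = w.pressure
    lo, hi = float(np.min(p)), float(np.max(p))
    if hi - lo <= 0:
        raise ValueError("flat waveform cannot be calibrated")
    scaled = brachial_DP + (p - lo) * (brachial_SP - brachial_DP) / (hi - lo)
    return replace(w, pressure=scaled, calibrated=True)


def _smooth(p: np.ndarray, window_frac: float = 0.05) -> np.ndarray:
    n = p.size
    win = max(5, int(round(window_frac * n)) | 1)
    win = min(win, n - 1 if (n - 1) % 2 else n - 2)
    return savgol_filter(p, window_length=win, polyorder=3, mode="wrap")


def foot_time(w: PressureWaveform) -> float:
    """Waveform foot (ms) by the intersecting-tangent method.

    The tangent through the point of maximum upslope is intersected with the
    horizontal line through the end-diastolic minimum.
    """
    t, p = w.time_ms, _smooth(w.pressure)
    dp = np.gradient(p, t)
    imin = int(np.argmin(p))
    # maximum upslope on the rising limb following the minimum (cyclic)
    order = np.roll(np.arange(t.size), -imin)
    rising = order[: max(3, t.size // 2)]
    imax = rising[int(np.argmax(dp[rising]))]
    slope = dp[imax]
    if slope <= 0:
        raise ValueError("no rising limb found; cannot locate the foot")
    t_cross = t[imax] - (p[imax] - p[imin]) / slope
    if t_cross < t[0]:
        t_cross += w.period_ms
    return float(t_cross)


def detect_landmarks(w: PressureWaveform, window_frac: float = 0.05) -> Landmarks:
    """Locate foot, systolic peak, shoulder, and dicrotic notch.

    The shoulder (inflection from the reflected wave) is taken from the sign
    structure of the fourth derivative of the smoothed waveform, the standard
    pulse-wave-analysis approach; the notch is the most prominent minimum of
    the smoothed derivative after the peak.  When no notch is detectable an
    ED estimate (40% of the cycle less a stiffness-free offset) is returned
    with ``notch_detected=False``.
    """
    t = w.time_ms
    p = _smooth(w.pressure, window_frac)
    n = t.size
    period = w.period_ms
    foot = foot_time(w)
    # work on a cycle re-based at the foot
    shift = int(np.searchsorted(t, foot % period))
    idx = np.roll(np.arange(n), -shift)
    ps = p[idx]
    ts = (t[idx] - t[shift % n]) % period
    ipk = int(np.argmax(ps))
    d1 = np.gradient(ps, ts[1] - ts[0])
    d4 = np.gradient(np.gradient(np.gradient(d1)))
    # shoulder: first zero-crossing of the 4th derivative in mid systole
    lo = max(2, int(0.08 * n))
    hi = max(lo + 2, int(0.45 * n))
    shoulder_i = None
    guard = max(2, n // 100)
    for i in range(lo, hi):
        if d4[i] * d4[i + 1] < 0 and abs(i - ipk) > guard:
            shoulder_i = i
            break
    if shoulder_i is None:
        shoulder_i = max(1, int(0.7 * ipk))
    # dicrotic notch: the incisura (local pressure minimum) when present,
    # otherwise the sharpest post-peak deceleration of the falling limb
    start = max(ipk + 2, int(0.2 * n))
    stop = int(0.75 * n)
    notch_i = None
    if stop - start > 4:
        seg_p = ps[start:stop]
        minima = [
            k
            for k in range(1, seg_p.size - 1)
            if seg_p[k] < seg_p[k - 1] and seg_p[k] <= seg_p[k + 1]
        ]
        if minima:
            notch_i = start + min(minima, key=lambda k: seg_p[k])
        else:
            seg = d1[start:stop]
            cand = [
                k
                for k in range(1, seg.size - 1)
                if seg[k] < seg[k - 1] and seg[k] <= seg[k + 1] and seg[k] < 0
            ]
            if cand:
                notch_i = start + min(cand, key=lambda k: seg[k])
    detected = notch_i is not None
    if not detected:
        notch_i = int(0.37 * n)
    wtype = "A" if shoulder_i <= ipk else "C"
    return Landmarks(
        foot=foot,
        systolic_peak=float(foot + ts[ipk]),
        shoulder=float(foot + ts[shoulder_i]),
        notch=float(foot + ts[notch_i]),
        notch_detected=detected,
        waveform_type=wtype,
    )


def augmentation_index(SP: float, DP: float, AP: float) -> float:
    """AI = (SP-DP)/(SP-DP-AP) x 100%.  AP = 0 gives exactly 100%."""
    pp = SP - DP
    if pp <= 0:
        raise ValueError("require SP > DP")
    if AP >= pp:
        raise ValueError("augmented pressure must be below pulse pressure")
    return pp / (pp - AP) * 100.0


def sevr(w: PressureWaveform, ED: float) -> float:
    """Diastolic over systolic pressure-time integral, x100 (percent).

    ``ED`` is the ejection duration in ms measured from the start of the
    waveform's time axis.
    """
    t, p = w.time_ms, w.pressure
    T = w.period_ms
    if not 0 < ED < T:
        raise ValueError("ED must fall inside the cycle")
    # split the piecewise-linear waveform exactly at ED (periodic closure at T)
    tt = np.unique(np.concatenate([t - t[0], [ED, T]]))
    pp = np.interp(tt, np.append(t - t[0], T), np.append(p, p[0]))
    k = int(np.searchsorted(tt, ED))
    a_sys = np.trapezoid(pp[: k + 1], tt[: k + 1])
    a_dia = np.trapezoid(pp[k:], tt[k:])
    return float(a_dia / a_sys * 100.0)


def waveform_indices(w: PressureWaveform, window_frac: float = 0.05) -> PWAIndices:
    """Full PWA index set from a calibrated single-cycle waveform."""
    lm = detect_landmarks(w, window_frac)
    p = w.pressure
    SP = float(np.max(p))
    DP = float(np.min(p))
    t, period = w.time_ms, w.period_ms

    def p_at(time):
        return float(
            np.interp(
                (time - t[0]) % period,
                np.append(t - t[0], period),
                np.append(p, p[0]),
            )
        )

    AP = p_at(lm.systolic_peak) - p_at(lm.shoulder)
    if lm.waveform_type == "C":
        AP = -abs(AP)
    ED = (lm.notch - lm.foot) % period
    # SEVR integrals are taken on the cycle starting at the foot
    shift = (lm.foot - t[0]) % period
    k = int(round(shift / w.dt_ms)) % t.size
    w_foot = PressureWaveform(
        time_ms=t, pressure=np.roll(p, -k), calibrated=w.calibrated, HR=w.HR
    )
    return PWAIndices(
        SP=SP,
        DP=DP,
        PP=SP - DP,
        AP=AP,
        AI=augmentation_index(SP, DP, AP),
        ED=float(ED),
        SEVR=sevr(w_foot, float(ED)),
        waveform_type=lm.waveform_type,
        notch_detected=lm.notch_detected,
    )


def pulse_wave_velocity(sim: SimulationResult, site_a, site_b) -> float:
    """Foot-to-foot pulse wave velocity (m/s) between two tree sites.

    Path length follows the vessels between the sites (which must lie on a
    common root-to-leaf path); transit time is the difference of the
    intersecting-tangent foot times of the two pressure waveforms.
    """
    dist_cm = path_length(sim.tree, site_a, site_b)  # raises if not on a path
    t, pa, _ = sim.site_series(site_a)
    _, pb, _ = sim.site_series(site_b)
    # drop the duplicated endpoint if present (periodic record)
    wa = PressureWaveform(time_ms=t[:-1], pressure=pa[:-1])
    wb = PressureWaveform(time_ms=t[:-1], pressure=pb[:-1])
    ta = foot_time(wa)
    tb = foot_time(wb)
    period = wa.period_ms
    transit = (tb - ta) % period
    if transit > period / 2:  # site order reversed
        transit = (ta - tb) % period
    dt_ms = wa.dt_ms
    if transit < dt_ms:
        raise ValueError(
            f"transit time {transit:.3f} ms below one sample ({dt_ms:.3f} ms); "
            "increase the output rate or separate the sites"
        )
    return float(dist_cm / (transit / 1000.0)) / 100.0
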