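"""Virtual hemodialysis (HD) and control cohorts for end-to-end testing.

The study design being emulated: each HD patient is recorded eight times —
two dialysis sessions (after a 3-day and a 2-day interdialytic break), each
sampled before start, after start, before end, and after end — while each
control subject is recorded once.  Recordings can be missing (the tonometry
quality-based exclusion is emulated as a flat missing-completely-at-random
rate, default 25/280).  Subject parameters are drawn from truncated normal
distributions matching the reported cohort means and SDs; dialysis lowers
large-artery stiffness (k3) transiently, with smaller transient reductions
of stroke volume and ejection-peak time.

Every recording stores its ground-truth parameters, so the full inverse
pipeline can be audited against known values.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import brentq
from scipy.stats import truncnorm

from .arterial_tree import ArterialTree, nominal_tree, scale_tree_to_height
from .hemodynamics import (
    NumericsConfig,
    PatientParameters,
    SimulationError,
    ConvergenceError,
    converge_to_periodic,
)
from .waveform_analysis import PressureWaveform

__all__ = [
    "ParameterDist",
    "PopulationSpec",
    "Recording",
    "Subject",
    "CohortDataset",
    "HD_POPULATION",
    "CONTROL_POPULATION",
    "sample_virtual_patient",
    "generate_recording",
    "generate_cohort_dataset",
    "save_dataset",
    "load_dataset",
]

HD_TIME_POINTS = ("before_start", "after_start", "before_end", "after_end")
HD_SESSIONS = ("3day", "2day")


@dataclass(frozen=True)
class ParameterDist:
    mean: float
    sd: float

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


def _truncated_normal(dist: ParameterDist, rng, lo_frac_sd=4.0):
    """Draw > 0 within [mean - 4 SD, mean + 4 SD], population mean preserved.

    When the positivity truncation cuts into the left tail it would bias the
    truncated mean above the reported value, so the parent location is
    shifted (solved numerically) to keep the truncated mean at ``dist.mean``.
    """
    if dist.sd == 0:
        if dist.mean <= 0:
            raise ValueError("degenerate distribution with non-positive mean")
        return dist.mean
    lo = max(1e-12, dist.mean - lo_frac_sd * dist.sd)
    hi = dist.mean + lo_frac_sd * dist.sd
    if lo >= hi:
        raise ValueError("infeasible truncation window")
    loc = _debiased_loc(dist.mean, dist.sd, lo, hi)
    a, b = (lo - loc) / dist.sd, (hi - loc) / dist.sd
    return float(truncnorm.rvs(a, b, loc=loc, scale=dist.sd, random_state=rng))


def _debiased_loc(target_mean, sd, lo, hi, _cache={}):
    key = (target_mean, sd, lo, hi)
    if key not in _cache:
        def trunc_mean(loc):
            a, b = (lo - loc) / sd, (hi - loc) / sd
            return truncnorm.mean(a, b, loc=loc, scale=sd)

        if abs(trunc_mean(target_mean) - target_mean) < 1e-9 * sd:
            _cache[key] = target_mean
        else:
            _cache[key] = float(
                brentq(lambda c: trunc_mean(c) - target_mean,
                       target_mean - 3.0 * sd, target_mean + sd, xtol=1e-9 * sd)
            )
    return _cache[key]


@dataclass(frozen=True)
class PopulationSpec:
    """Per-group parameter and covariate distributions.

    Defaults (see :data:`HD_POPULATION` / :data:`CONTROL_POPULATION`) follow
    the reported cohort statistics; session effects are multiplicative
    factors applied to a subject's baseline value at each HD time point.
    """

    k1: ParameterDist
    k3: ParameterDist
    CO: ParameterDist
    tau: ParameterDist
    S_R: ParameterDist
    S_C: ParameterDist
    age: ParameterDist
    height: ParameterDist
    weight: ParameterDist
    HR: ParameterDist
    brachial_SP: ParameterDist
    brachial_DP: ParameterDist
    male_fraction: float = 0.43
    missing_probability: float = 25.0 / 280.0
    # time-point multipliers on k3 (transient intradialytic stiffness drop)
    k3_session_factors: dict = field(
        default_factory=lambda: {
            "before_start": 16.44 / 14.51,
            "after_start": 1.00,
            "before_end": 9.92 / 14.51,
            "after_end": 0.95,
            "single": 1.0,
        }
    )
    # milder transient reductions of stroke volume (via CO) and tau
    co_session_factors: dict = field(
        default_factory=lambda: {
            "before_start": 1.0,
            "after_start": 0.97,
            "before_end": 0.92,
            "after_end": 0.97,
            "single": 1.0,
        }
    )
    tau_session_factors: dict = field(
        default_factory=lambda: {
            "before_start": 1.0,
            "after_start": 0.97,
            "before_end": 0.93,
            "after_end": 0.98,
            "single": 1.0,
        }
    )

    def __post_init__(self):
        if not 0 <= self.missing_probability <= 1:
            raise ValueError("missing_probability must be in [0, 1]")
        if not 0 <= self.male_fraction <= 1:
            raise ValueError("male_fraction must be in [0, 1]")


# Cohort means/SDs as reported for the HD group; covariates from the group
# characteristics table.  Brachial pressures and HR are typical-dialysis
# conventions (not tabulated in the source).
HD_POPULATION = PopulationSpec(
    k1=ParameterDist(2.28e7, 1.73e7),
    k3=ParameterDist(14.51e5, 9.03e5),
    CO=ParameterDist(3.56, 0.8),
    tau=ParameterDist(101.08, 20.78),
    S_R=ParameterDist(1.34, 0.56),
    S_C=ParameterDist(13.57, 4.34),
    age=ParameterDist(61.2, 14.3),
    height=ParameterDist(167.9, 9.4),
    weight=ParameterDist(72.2, 19.9),
    HR=ParameterDist(72.0, 10.0),
    brachial_SP=ParameterDist(132.0, 18.0),
    brachial_DP=ParameterDist(76.0, 10.0),
    male_fraction=0.43,
)

# Healthy controls: stiffness ~60% lower than the pre-dialysis HD values,
# similar cardiac output, lower capillary-bed compliance scaling.
CONTROL_POPULATION = PopulationSpec(
    k1=ParameterDist(1.40e7, 0.9e7),
    k3=ParameterDist(8.9e5, 4.5e5),
    CO=ParameterDist(3.6, 0.8),
    tau=ParameterDist(104.0, 18.0),
    S_R=ParameterDist(1.30, 0.5),
    S_C=ParameterDist(9.5, 3.5),
    age=ParameterDist(42.7, 9.3),
    height=ParameterDist(173.4, 10.8),
    weight=ParameterDist(78.3, 19.1),
    HR=ParameterDist(68.0, 9.0),
    brachial_SP=ParameterDist(122.0, 12.0),
    brachial_DP=ParameterDist(76.0, 8.0),
    male_fraction=0.47,
    missing_probability=0.0,
)


@dataclass
class Subject:
    id: str
    group: str  # "HD" | "control"
    male: bool
    age: float
    height: float
    weight: float
    params: PatientParameters  # baseline truth


@dataclass
class Recording:
    subject_id: str
    session: str  # "3day" | "2day" | "none"
    time_point: str  # HD_TIME_POINTS or "single"
    missing: bool
    truth: PatientParameters | None
    waveform: PressureWaveform | None
    missing_cause: str | None = None


@dataclass
class CohortDataset:
    subjects: list
    recordings: list
    seed: int
    device_rate_hz: float
    noise_fraction: float

    def scheduled(self, group: str | None = None) -> list:
        if group is None:
            return self.recordings
        ids = {s.id for s in self.subjects if s.group == group}
        return [r for r in self.recordings if r.subject_id in ids]

    def n_missing(self, group: str | None = None) -> int:
        return sum(r.missing for r in self.scheduled(group))


def sample_virtual_patient(
    spec: PopulationSpec, group: str, rng, subject_id: str = "S0"
) -> Subject:
    """Draw one subject: six model parameters plus covariates."""
    rng = np.random.default_rng(rng)
    male = bool(rng.random() < spec.male_fraction)
    draws = {
        name: _truncated_normal(getattr(spec, name), rng)
        for name in (
            "k1", "k3", "CO", "tau", "S_R", "S_C",
            "age", "height", "weight", "HR", "brachial_SP", "brachial_DP",
        )
    }
    height = float(np.clip(draws["height"], 130.0, 210.0))
    sp = max(draws["brachial_SP"], draws["brachial_DP"] + 20.0)
    hr = float(np.clip(draws["HR"], 45.0, 110.0))
    ed = 0.33 * 60000.0 / hr
    tau = float(np.clip(draws["tau"], 40.0, 0.8 * ed))
    params = PatientParameters(
        k1=draws["k1"], k3=draws["k3"], CO=draws["CO"], tau=tau,
        S_R=draws["S_R"], S_C=draws["S_C"], HR=hr, height=height,
        brachial_SP=sp, brachial_DP=draws["brachial_DP"],
    )
    return Subject(
        id=subject_id, group=group, male=male, age=draws["age"],
        height=height, weight=draws["weight"], params=params,
    )


def _session_params(subject: Subject, spec: PopulationSpec,
                    time_point: str) -> PatientParameters:
    base = subject.params
    kw = {
        "k1": base.k1,
        "k3": base.k3 * spec.k3_session_factors.get(time_point, 1.0),
        "CO": base.CO * spec.co_session_factors.get(time_point, 1.0),
        "tau": base.tau * spec.tau_session_factors.get(time_point, 1.0),
        "S_R": base.S_R,
        "S_C": base.S_C,
        "HR": base.HR,
        "height": base.height,
        "brachial_SP": base.brachial_SP,
        "brachial_DP": base.brachial_DP,
    }
    return PatientParameters(**kw)


def generate_recording(
    subject: Subject,
    time_point: str,
    spec: PopulationSpec,
    rng,
    tree: ArterialTree | None = None,
    session: str = "none",
    device_rate_hz: float = 128.0,
    noise_fraction: float = 0.015,
    baseline_wander: float = 0.5,
    numerics: NumericsConfig | None = None,
    site: str = "radial_distal",
) -> Recording:
    """Run the forward model for one recording slot and emulate the device.

    The simulated radial waveform is resampled at the device rate; Gaussian
    noise proportional to the pulse amplitude and a slow baseline wander are
    added.  Ground-truth parameters are attached.
    """
    rng = np.random.default_rng(rng)
    tree = tree if tree is not None else nominal_tree()
    numerics = numerics or NumericsConfig(dx_cm=1.25, output_dt_ms=2.0,
                                          tol_mmhg=0.5, max_cycles=15)
    truth = _session_params(subject, spec, time_point)
    try:
        scaled = scale_tree_to_height(tree, subject.height)
        sim = converge_to_periodic(scaled, truth, config=numerics)
    except (SimulationError, ConvergenceError, ValueError) as exc:
        return Recording(
            subject_id=subject.id, session=session, time_point=time_point,
            missing=True, truth=truth, waveform=None,
            missing_cause=f"solver failure: {exc}",
        )
    t, p, _ = sim.site_series(site)
    T = truth.cycle_ms
    dt_dev = 1000.0 / device_rate_hz
    t_dev = np.arange(0.0, T - 1e-9, dt_dev)
    p_dev = np.interp(t_dev % (t[-1] - t[0] + (t[1] - t[0])),
                      np.append(t - t[0], T), np.append(p, p[0]))
    if noise_fraction > 0:
        amp = float(np.max(p_dev) - np.min(p_dev))
        p_dev = p_dev + rng.normal(0.0, noise_fraction * amp, p_dev.size)
    if baseline_wander > 0 and noise_fraction > 0:
        phase = rng.uniform(0, 2 * np.pi)
        p_dev = p_dev + baseline_wander * np.sin(2 * np.pi * t_dev / T + phase)
    wf = PressureWaveform(time_ms=t_dev, pressure=p_dev, calibrated=True,
                          HR=truth.HR)
    return Recording(
        subject_id=subject.id, session=session, time_point=time_point,
        missing=False, truth=truth, waveform=wf,
    )


def generate_cohort_dataset(
    n_hd: int,
    n_control: int,
    hd_spec: PopulationSpec = HD_POPULATION,
    control_spec: PopulationSpec = CONTROL_POPULATION,
    seed: int = 0,
    with_waveforms: bool = True,
    tree: ArterialTree | None = None,
    device_rate_hz: float = 128.0,
    noise_fraction: float = 0.015,
    numerics: NumericsConfig | None = None,
) -> CohortDataset:
    """Full study-design dataset: 8 scheduled slots per HD subject, 1 per control.

    Each HD slot is independently missing with ``hd_spec.missing_probability``.
    With ``with_waveforms=False`` only the design, truth parameters and
    missingness flags are generated (no solver runs).
    """
    if n_hd < 0 or n_control < 0:
        raise ValueError("cohort sizes must be non-negative")
    rng = np.random.default_rng(seed)
    tree = tree if tree is not None else nominal_tree()
    subjects, recordings = [], []
    for i in range(n_hd):
        s = sample_virtual_patient(hd_spec, "HD", rng, subject_id=f"HD{i:03d}")
        subjects.append(s)
        for session in HD_SESSIONS:
            for tp in HD_TIME_POINTS:
                if rng.random() < hd_spec.missing_probability:
                    recordings.append(Recording(
                        subject_id=s.id, session=session, time_point=tp,
                        missing=True, truth=_session_params(s, hd_spec, tp),
                        waveform=None, missing_cause="quality exclusion",
                    ))
                elif with_waveforms:
                    recordings.append(generate_recording(
                        s, tp, hd_spec, rng, tree=tree, session=session,
                        device_rate_hz=device_rate_hz,
                        noise_fraction=noise_fraction, numerics=numerics,
                    ))
                else:
                    recordings.append(Recording(
                        subject_id=s.id, session=session, time_point=tp,
                        missing=False, truth=_session_params(s, hd_spec, tp),
                        waveform=None,
                    ))
    for i in range(n_control):
        s = sample_virtual_patient(
            control_spec, "control", rng, subject_id=f"C{i:03d}"
        )
        subjects.append(s)
        if rng.random() < control_spec.missing_probability:
            recordings.append(Recording(
                subject_id=s.id, session="none", time_point="single",
                missing=True, truth=s.params, waveform=None,
                missing_cause="quality exclusion",
            ))
        elif with_waveforms:
            recordings.append(generate_recording(
                s, "single", control_spec, rng, tree=tree, session="none",
                device_rate_hz=device_rate_hz,
                noise_fraction=noise_fraction, numerics=numerics,
            ))
        else:
            recordings.append(Recording(
                subject_id=s.id, session="none", time_point="single",
                missing=False, truth=s.params, waveform=None,
            ))
    return CohortDataset(
        subjects=subjects, recordings=recordings, seed=seed,
        device_rate_hz=device_rate_hz, noise_fraction=noise_fraction,
    )


# ---------------------------------------------------------------------------
# on-disk format: manifest.json + one CSV per non-missing recording


def _params_to_dict(p: PatientParameters | None):
    if p is None:
        return None
    return {
        k: getattr(p, k)
        for k in ("k1", "k3", "CO", "tau", "S_R", "S_C", "HR", "ED",
                  "height", "brachial_SP", "brachial_DP")
    }


def _params_from_dict(d):
    return None if d is None else PatientParameters(**d)


def save_dataset(ds: CohortDataset, path: str | Path) -> None:
    """Write manifest.json plus per-recording waveform CSVs under ``path``."""
    from .cli_io import write_waveform_csv

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": ds.seed,
        "device_rate_hz": ds.device_rate_hz,
        "noise_fraction": ds.noise_fraction,
        "subjects": [
            {**asdict(s), "params": _params_to_dict(s.params)}
            for s in ds.subjects
        ],
        "recordings": [],
    }
    for k, r in enumerate(ds.recordings):
        fname = None
        if r.waveform is not None:
            fname = f"rec_{k:04d}_{r.subject_id}_{r.session}_{r.time_point}.csv"
            write_waveform_csv(r.waveform, path / fname)
        manifest["recordings"].append({
            "subject_id": r.subject_id,
            "session": r.session,
            "time_point": r.time_point,
            "missing": r.missing,
            "missing_cause": r.missing_cause,
            "truth": _params_to_dict(r.truth),
            "waveform_file": fname,
            "HR": None if r.waveform is None else r.waveform.HR,
        })
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1))


def load_dataset(path: str | Path) -> CohortDataset:
    """Inverse of :func:`save_dataset`; waveforms round-trip bit-exactly."""
    from .cli_io import read_waveform_csv

    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    subjects = [
        Subject(
            id=s["id"], group=s["group"], male=s["male"], age=s["age"],
            height=s["height"], weight=s["weight"],
            params=_params_from_dict(s["params"]),
        )
        for s in manifest["subjects"]
    ]
    recordings = []
    for r in manifest["recordings"]:
        wf = None
        if r["waveform_file"]:
            wf = read_waveform_csv(path / r["waveform_file"])
            wf = PressureWaveform(time_ms=wf.time_ms, pressure=wf.pressure,
                                  calibrated=True, HR=r["HR"])
        recordings.append(Recording(
            subject_id=r["subject_id"], session=r["session"],
            time_point=r["time_point"], missing=r["missing"],
            truth=_params_from_dict(r["truth"]), waveform=wf,
            missing_cause=r.get("missing_cause"),
        ))
    return CohortDataset(
        subjects=subjects, recordings=recordings, seed=manifest["seed"],
        device_rate_hz=manifest["device_rate_hz"],
        noise_fraction=manifest["noise_fraction"],
    )
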