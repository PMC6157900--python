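"""Estimation of the six patient-specific parameters from a radial waveform.

The inverse problem minimises the relative discrepancy between the measured
(calibrated) radial pressure waveform and the model-predicted waveform at
the distal radial site, over (k1, k3, CO, tau, S_R, S_C).  Waveforms are
compared after aligning their feet, so a uniform time shift of the
recording does not change the objective.

The waveform constrains the *composite* wall stiffness at the recording
site, k1 exp(-k2 r_rad) + k3, much more strongly than k1 and k3
separately: trading k1 against k3 (with small compensations in CO, S_R and
S_C) changes the waveform only through subtle timing features, producing a
long, shallow, curved valley in parameter space with distinct local
branches.  The search therefore combines a constriction-coefficient
particle swarm with an explicit profile walk over k1: the walk is anchored
at the k1 = 0 edge, re-optimises the five well-conditioned parameters at
each k1 grid point (simplex + quasi-Newton with finite differences, warm
started by linear extrapolation along the walk), and stops once the
profiled minimum has clearly passed.  Simulations inside the objective run
a fixed cycle count so the objective depends smoothly on the parameters.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.optimize import minimize

from .arterial_tree import ArterialTree, scale_tree_to_height
from .hemodynamics import (
    ConvergenceError,
    HemoConstants,
    NumericsConfig,
    PatientParameters,
    SimulationError,
    converge_to_periodic,
)
from .waveform_analysis import PressureWaveform, foot_time

__all__ = [
    "FitConfig",
    "FitResult",
    "objective_error",
    "fit_patient",
    "economy_fit_config",
    "FitFailure",
]

PARAM_NAMES = ("k1", "k3", "CO", "tau", "S_R", "S_C")

# physiological boxes: printed cohort means +/- 4 SD, truncated to positivity
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "k1": (0.0, 9.2e7),
    "k3": (1.0e5, 5.06e6),
    "CO": (0.5, 6.8),
    "tau": (20.0, 185.0),
    "S_R": (0.2, 3.6),
    "S_C": (1.0, 31.0),
}

SENTINEL_ERROR = 999.0  # % returned when a candidate simulation is unstable


class FitFailure(RuntimeError):
    pass


def economy_fit_config(seed: int = 0) -> "FitConfig":
    """Reduced-cost configuration for many-fit experiments.

    Keeps the full swarm (global coverage is what fails first) but shortens
    the refinement stages and runs the solver on a coarse grid with a fixed
    five-cycle horizon.  Roughly three times faster than the defaults.
    """
    return FitConfig(
        seed=seed, particles=20, iterations=30, refine_nm_maxfev=100,
        profile_step=0.08, profile_max_points=12, profile_nm_maxfev=80,
        profile_lbfgs_maxfun=130, profile_pred_maxfun=70,
        final_nm_maxfev=120, final_lbfgs_maxfun=100,
        numerics=NumericsConfig(dx_cm=1.75, output_dt_ms=2.0,
                                fixed_cycles=5),
    )


@dataclass(frozen=True)
class FitConfig:
    bounds: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDS)
    )
    particles: int = 20
    iterations: int = 30
    chi: float = 0.7298  # constriction coefficient
    c1: float = 2.05
    c2: float = 2.05
    refine_nm_maxfev: int = 120
    profile_step: float = 0.08  # k1 walk step (normalised coordinates)
    profile_max_points: int = 14
    profile_nm_maxfev: int = 90  # simplex part of an anchor solve
    profile_lbfgs_maxfun: int = 140  # quasi-Newton part of an anchor solve
    profile_pred_maxfun: int = 70  # quasi-Newton budget at predicted points
    profile_eps: float = 5e-5  # finite-difference step (normalised coords)
    final_nm_maxfev: int = 150
    final_lbfgs_maxfun: int = 100
    seed: int = 0
    norm: str = "mae"  # or "l2"
    site: str = "radial_distal"
    numerics: NumericsConfig = field(
        default_factory=lambda: NumericsConfig(
            dx_cm=1.25, output_dt_ms=2.0, fixed_cycles=7
        )
    )

    def __post_init__(self):
        if self.particles < 5:
            raise ValueError("need at least 5 particles")
        for name in PARAM_NAMES:
            lo, hi = self.bounds[name]
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"invalid bounds for {name}")
        if self.norm not in ("mae", "l2"):
            raise ValueError("norm must be 'mae' or 'l2'")

    @property
    def config_hash(self) -> str:
        payload = {
            "bounds": {k: list(v) for k, v in sorted(self.bounds.items())},
            "particles": self.particles,
            "iterations": self.iterations,
            "chi": self.chi,
            "c1": self.c1,
            "c2": self.c2,
            "profile_step": self.profile_step,
            "norm": self.norm,
            "site": self.site,
            "dx_cm": self.numerics.dx_cm,
        }
        return hashlib.sha256(json.dumps(payload).encode()).hexdigest()[:12]


@dataclass
class FitResult:
    params: PatientParameters
    relative_error: float  # percent
    objective_trace: list
    converged: bool
    seed: int
    config_hash: str
    evaluations: int

    def to_dict(self) -> dict:
        d = {name: getattr(self.params, name) for name in PARAM_NAMES}
        d.update(
            relative_error=self.relative_error,
            converged=self.converged,
            seed=self.seed,
            config_hash=self.config_hash,
            evaluations=self.evaluations,
        )
        return d


def _assemble(values, meta: Mapping[str, float]) -> PatientParameters:
    kw = dict(zip(PARAM_NAMES, (float(v) for v in values)))
    for key in ("HR", "ED", "height", "brachial_SP", "brachial_DP"):
        if key in meta and meta[key] is not None:
            kw[key] = meta[key]
    return PatientParameters(**kw)


def waveform_error(
    sim_t: np.ndarray, sim_p: np.ndarray, measured: PressureWaveform,
    norm: str = "mae",
) -> float:
    """Relative error (%) between a simulated and a measured waveform.

    Both are treated as periodic; the simulated trace is foot-aligned to the
    measurement before comparison, and the error is normalised by the mean
    measured pressure.
    """
    w_sim = PressureWaveform(time_ms=sim_t, pressure=sim_p)
    shift = foot_time(w_sim) - foot_time(measured)
    period = w_sim.period_ms
    tq = (measured.time_ms - measured.time_ms[0] + shift) % period
    tbase = np.append(sim_t - sim_t[0], period)
    pbase = np.append(sim_p, sim_p[0])
    p_sim = np.interp(tq, tbase, pbase)
    diff = p_sim - measured.pressure
    denom = float(np.mean(measured.pressure))
    if norm == "mae":
        return float(np.mean(np.abs(diff)) / denom * 100.0)
    return float(np.sqrt(np.mean(diff**2)) / denom * 100.0)


def objective_error(
    params: PatientParameters,
    measured: PressureWaveform,
    tree: ArterialTree,
    constants: HemoConstants | None = None,
    config: FitConfig | None = None,
) -> float:
    """Fit objective: relative waveform error (%) at the radial site.

    Unstable or non-convergent simulations yield a large finite sentinel so
    a surrounding search can continue.
    """
    config = config or FitConfig()
    try:
        sim = converge_to_periodic(tree, params, constants, config.numerics)
    except (SimulationError, ConvergenceError, ValueError):
        return SENTINEL_ERROR
    t, p, _ = sim.site_series(config.site)
    return waveform_error(t[:-1], p[:-1], measured, config.norm)


def fit_patient(
    measured: PressureWaveform,
    meta: Mapping[str, float],
    tree: ArterialTree,
    config: FitConfig | None = None,
    constants: HemoConstants | None = None,
    x0: Mapping[str, float] | None = None,
) -> FitResult:
    """Estimate (k1, k3, CO, tau, S_R, S_C) from a calibrated radial waveform.

    ``meta`` supplies the fixed covariates (HR, height, brachial_SP,
    brachial_DP, optionally ED in ms).  The tree is scaled to the subject's
    height before any simulation.  Deterministic for a given seed; the
    refinement stages never accept a point worse than the current best.
    """
    config = config or FitConfig()
    if not measured.calibrated:
        raise ValueError("measured waveform must be calibrated to brachial pressure")
    if "height" in meta and meta["height"] is not None:
        tree = scale_tree_to_height(tree, meta["height"])
    lo = np.array([config.bounds[n][0] for n in PARAM_NAMES])
    hi = np.array([config.bounds[n][1] for n in PARAM_NAMES])
    span = hi - lo
    # tau must stay below the subject's ejection duration
    tau_cap = None
    if meta.get("ED"):
        tau_cap = 0.95 * meta["ED"]
    evals = 0

    def f(z: np.ndarray) -> float:
        nonlocal evals
        evals += 1
        vals = lo + np.clip(z, 0.0, 1.0) * span
        if tau_cap is not None:
            vals[3] = min(vals[3], tau_cap)
        try:
            params = _assemble(vals, meta)
        except ValueError:
            return SENTINEL_ERROR
        return objective_error(params, measured, tree, constants, config)

    rng = np.random.default_rng(config.seed)
    npart = config.particles
    X = rng.random((npart, 6))
    if x0 is not None:
        X[0] = np.clip(
            (np.array([x0[n] for n in PARAM_NAMES]) - lo) / span, 0.0, 1.0)
    V = 0.1 * (rng.random((npart, 6)) - 0.5)
    pbest = X.copy()
    pval = np.array([f(x) for x in X])
    g = int(np.argmin(pval))
    gbest, gval = pbest[g].copy(), float(pval[g])
    trace = [gval]
    for _ in range(config.iterations):
        r1 = rng.random((npart, 6))
        r2 = rng.random((npart, 6))
        V = config.chi * (
            V + config.c1 * r1 * (pbest - X) + config.c2 * r2 * (gbest - X)
        )
        X = X + V
        # reflect at the box edges
        over = X > 1.0
        under = X < 0.0
        X[over] = 2.0 - X[over]
        X[under] = -X[under]
        X = np.clip(X, 0.0, 1.0)
        V[over | under] *= -0.5
        for i in range(npart):
            val = f(X[i])
            if val < pval[i]:
                pval[i] = val
                pbest[i] = X[i].copy()
                if val < gval:
                    gval = float(val)
                    gbest = X[i].copy()
        trace.append(gval)

    def accept(z, val):
        nonlocal gbest, gval
        if val <= gval:
            gbest, gval = np.clip(np.asarray(z, float), 0.0, 1.0), float(val)

    # local simplex pass to settle onto the valley floor
    if gval > 1e-6:
        res = minimize(
            f, gbest, method="Nelder-Mead",
            options={"maxfev": config.refine_nm_maxfev, "xatol": 1e-3,
                     "fatol": 1e-6,
                     "initial_simplex": _initial_simplex(gbest, 0.02)},
        )
        accept(res.x, res.fun)
    trace.append(gval)

    # CO and S_R jointly set the mean pressure, forming their own exchange
    # valley; the conditional solves therefore work in rotated coordinates
    # (k3, log CO + log S_R, log CO - log S_R, tau, S_C), which makes that
    # trade-off an axis direction
    co_lo, co_hi = lo[2], hi[2]
    sr_lo, sr_hi = lo[4], hi[4]

    def _to_rot(y5):
        co = co_lo + np.clip(y5[1], 0, 1) * (co_hi - co_lo)
        sr = sr_lo + np.clip(y5[3], 0, 1) * (sr_hi - sr_lo)
        u, v = np.log(co), np.log(sr)
        return np.array([y5[0], u + v, u - v, y5[2], y5[4]])

    def _from_rot(yr):
        u = 0.5 * (yr[1] + yr[2])
        v = 0.5 * (yr[1] - yr[2])
        co_n = (np.exp(u) - co_lo) / (co_hi - co_lo)
        sr_n = (np.exp(v) - sr_lo) / (sr_hi - sr_lo)
        return np.clip(np.array([yr[0], co_n, yr[3], sr_n, yr[4]]), 0.0, 1.0)

    rot_bounds = [
        (0.0, 1.0),
        (np.log(co_lo) + np.log(sr_lo), np.log(co_hi) + np.log(sr_hi)),
        (np.log(co_lo) - np.log(sr_hi), np.log(co_hi) - np.log(sr_lo)),
        (0.0, 1.0),
        (0.0, 1.0),
    ]

    # conditional solve: optimise the five remaining coordinates at a fixed
    # k1 coordinate; ``full`` runs simplex + quasi-Newton (used at the
    # anchor and zoom), predicted points run quasi-Newton only
    def conditional(k1n, y0, full):
        def g5(yr):
            return f(np.concatenate([[k1n], _from_rot(yr)]))

        yr = _to_rot(np.clip(y0, 0.0, 1.0))
        if full:
            simplex = np.tile(yr, (6, 1))
            for k in range(5):
                simplex[k + 1, k] = yr[k] + 0.03
            r = minimize(
                g5, yr, method="Nelder-Mead",
                options={"maxfev": config.profile_nm_maxfev, "xatol": 1e-3,
                         "fatol": 1e-7, "initial_simplex": simplex},
            )
            yr = r.x
        r2 = minimize(
            g5, yr, method="L-BFGS-B", bounds=rot_bounds,
            options={"maxfun": (config.profile_lbfgs_maxfun if full
                                else config.profile_pred_maxfun),
                     "eps": config.profile_eps,
                     "ftol": 1e-14, "gtol": 1e-12},
        )
        return np.concatenate([[k1n], _from_rot(r2.x)]), float(r2.fun)

    # anchored profile walk: solve the k1 = 0 edge thoroughly, then walk k1
    # upward with linear extrapolation of the five tracked coordinates,
    # stopping after the profiled minimum has clearly passed
    if config.profile_max_points > 0 and gval > 1e-6:
        z0, f0 = conditional(0.0, gbest[1:], full=True)
        accept(z0, f0)
        walk = [(0.0, z0[1:].copy(), f0)]
        rises = 0
        k1n = 0.0
        while len(walk) < config.profile_max_points:
            k1n = k1n + config.profile_step
            if k1n > 1.0 + 1e-9:
                break
            k1n = min(k1n, 1.0)
            if len(walk) >= 2:
                (ka, ya, _), (kb, yb, _) = walk[-2], walk[-1]
                ypred = yb + (yb - ya) * ((k1n - kb) / (kb - ka))
                z, fv = conditional(k1n, ypred, full=False)
            else:
                z, fv = conditional(k1n, walk[-1][1], full=True)
            accept(z, fv)
            if fv >= walk[-1][2]:
                rises += 1
            else:
                rises = 0
            walk.append((k1n, z[1:].copy(), fv))
            if rises >= 3:
                break
        # localise the profiled minimum by a least-squares parabola through
        # the walked points around it (their spacing gives far more contrast
        # than the conditional-solve noise), then solve there thoroughly
        ks = np.array([w[0] for w in walk])
        fs = np.array([w[2] for w in walk])
        bi = int(np.argmin(fs))
        near = np.abs(ks - ks[bi]) <= 2.1 * config.profile_step
        if near.sum() >= 3:
            coef = np.polyfit(ks[near], fs[near], 2)
            if coef[0] > 0:
                kv = float(np.clip(-coef[1] / (2 * coef[0]),
                                   max(0.0, ks[bi] - config.profile_step),
                                   min(1.0, ks[bi] + config.profile_step)))
                z, fv = conditional(kv, walk[bi][1], full=True)
                accept(z, fv)
        trace.append(gval)

    # final polish in all six coordinates: simplex, then bounded quasi-Newton
    if gval > 1e-6:
        res = minimize(
            f, gbest, method="Nelder-Mead",
            options={"maxfev": config.final_nm_maxfev, "xatol": 3e-4,
                     "fatol": 1e-8,
                     "initial_simplex": _initial_simplex(gbest, 0.01)},
        )
        accept(res.x, res.fun)
    if gval > 1e-6 and config.final_lbfgs_maxfun > 0:
        def g6(w):
            return f(np.concatenate([[w[0]], _from_rot(w[1:])]))

        w0 = np.concatenate([[gbest[0]], _to_rot(gbest[1:])])
        res = minimize(
            g6, w0, method="L-BFGS-B", bounds=[(0.0, 1.0)] + rot_bounds,
            options={"maxfun": config.final_lbfgs_maxfun,
                     "eps": 2e-5, "ftol": 1e-15, "gtol": 1e-13},
        )
        if res.fun <= gval:
            gbest = np.concatenate([[np.clip(res.x[0], 0, 1)],
                                    _from_rot(res.x[1:])])
            gval = float(res.fun)
    trace.append(gval)
    if gval >= SENTINEL_ERROR:
        raise FitFailure(
            "every candidate simulation was unstable; check the recording "
            "calibration and parameter bounds"
        )
    vals = lo + np.clip(gbest, 0.0, 1.0) * span
    if tau_cap is not None:
        vals[3] = min(vals[3], tau_cap)
    best = _assemble(vals, meta)
    return FitResult(
        params=best,
        relative_error=gval,
        objective_trace=trace,
        converged=bool(gval < SENTINEL_ERROR),
        seed=config.seed,
        config_hash=config.config_hash,
        evaluations=evals,
    )


def _initial_simplex(x: np.ndarray, step: float) -> np.ndarray:
    simplex = np.tile(x, (7, 1))
    for k in range(6):
        simplex[k + 1, k] = min(1.0, max(0.0, x[k] + (step if x[k] < 0.5 else -step)))
    return simplex


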