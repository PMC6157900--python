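"""Forward simulation of pulse-wave propagation on an arterial tree.

The blood is treated as an incompressible Newtonian fluid in impermeable,
axisymmetric elastic vessels.  Each terminal drains into a three-element
Windkessel whose nominal resistances and compliances are scaled uniformly by
the patient parameters ``S_R`` and ``S_C``.  The heart is represented by a
prescribed ejection flow at the ascending-aorta inlet: a smooth beta-shaped
pulse with peak at ``tau`` (ms), zero beyond the ejection duration ``ED``,
and area equal to the stroke volume ``SV = CO/HR``.

The hyperbolic system is advanced with a two-step Lax-Wendroff scheme (see
``_kernel``); :func:`converge_to_periodic` repeats cycles until the root
pressure trace is periodic to a configurable tolerance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import beta as beta_fn

from . import _kernel
from .arterial_tree import ArterialTree, WallModel, wall_stiffness
from .units import LMIN_TO_CGS, MMHG_TO_CGS

__all__ = [
    "HemoConstants",
    "WindkesselBC",
    "PatientParameters",
    "NumericsConfig",
    "SimulationResult",
    "inflow_profile",
    "windkessel_step",
    "simulate_cycle",
    "converge_to_periodic",
    "SimulationError",
    "ConvergenceError",
]


class SimulationError(RuntimeError):
    pass


class ConvergenceError(SimulationError):
    def __init__(self, msg, residuals=None):
        super().__init__(msg)
        self.residuals = residuals or []


@dataclass(frozen=True)
class HemoConstants:
    """Fixed fluid and friction constants (CGS)."""

    rho: float = 1.055  # g/cm^3
    mu: float = 0.049  # g/(cm s)
    delta: float = 0.086  # cm, boundary-layer thickness of the friction model

    def __post_init__(self):
        if min(self.rho, self.mu, self.delta) <= 0:
            raise ValueError("all hemodynamic constants must be positive")

    @property
    def nu(self) -> float:
        return self.mu / self.rho

    @property
    def friction_coefficient(self) -> float:
        """cf in the momentum sink -cf * q / sqrt(A)."""
        return 2.0 * math.sqrt(math.pi) * self.nu / self.delta


@dataclass(frozen=True)
class WindkesselBC:
    """Three-element Windkessel: R1 proximal, R2 distal (dyn s/cm^5), C (cm^5/dyn)."""

    R1: float
    R2: float
    C: float
    p_out: float = 5.0  # mmHg, venous pressure

    def __post_init__(self):
        if min(self.R1, self.R2, self.C) <= 0:
            raise ValueError("R1, R2, C must be positive")


def windkessel_step(p_c: float, q_in: float, bc: WindkesselBC, dt: float):
    """Advance the Windkessel capacitor pressure by ``dt`` seconds.

    ``q_in`` (cm^3/s) is held constant over the step, so the capacitor
    relaxes exactly exponentially with time constant ``R2*C`` towards
    ``p_out + q_in*R2``.  Returns ``(p_terminal, p_c_new)`` in dyn/cm^2
    (``p_c`` is the capacitor pressure, also dyn/cm^2).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    p_out_c = bc.p_out * MMHG_TO_CGS
    p_inf = p_out_c + q_in * bc.R2
    p_c_new = p_inf + (p_c - p_inf) * math.exp(-dt / (bc.R2 * bc.C))
    return p_c_new + bc.R1 * q_in, p_c_new


@dataclass(frozen=True)
class PatientParameters:
    """The six estimated parameters plus fixed per-subject covariates.

    k1, k3 in g s^-2 cm^-1; CO in l/min; tau (heart-ejection peak time) in
    ms; S_R and S_C dimensionless scalings of the nominal terminal
    resistances and compliances; HR in beats/min; ED (ejection duration,
    ms) defaults to a third of the cardiac cycle; height in cm; brachial
    pressures in mmHg.
    """

    k1: float
    k3: float
    CO: float
    tau: float
    S_R: float
    S_C: float
    HR: float = 70.0
    ED: float | None = None
    height: float = 176.0
    brachial_SP: float = 120.0
    brachial_DP: float = 80.0

    def __post_init__(self):
        if min(self.k3, self.tau, self.S_R, self.S_C, self.HR, self.height) <= 0:
            raise ValueError("parameters must be positive")
        if self.k1 < 0 or self.CO < 0:
            raise ValueError("k1 and CO must be non-negative")
        if not self.brachial_SP > self.brachial_DP > 0:
            raise ValueError("require brachial_SP > brachial_DP > 0")
        T = self.cycle_ms
        ed = self.ejection_duration
        if not self.tau < ed < T:
            raise ValueError(
                f"require tau ({self.tau} ms) < ED ({ed} ms) < cycle ({T:.1f} ms)"
            )

    @property
    def cycle_ms(self) -> float:
        return 60000.0 / self.HR

    @property
    def ejection_duration(self) -> float:
        """ED in ms (default: a third of the cycle when not measured)."""
        return self.ED if self.ED is not None else 0.33 * self.cycle_ms

    @property
    def stroke_volume(self) -> float:
        """SV = CO/HR in ml."""
        return self.CO * 1000.0 / self.HR

    @property
    def wall(self) -> WallModel:
        return WallModel(k1=self.k1, k3=self.k3)


_INFLOW_KAPPA = 5.0  # total beta-pulse exponent; sets ejection-curve smoothness


def inflow_profile(t_ms, params: PatientParameters):
    """Heart-ejection inflow q (cm^3/s) at time ``t_ms`` within the cycle.

    A beta-shaped pulse q(s) ∝ s^a (1-s)^b on s = t/ED with its single
    interior maximum exactly at t = tau, zero for t >= ED, and integral over
    the cycle equal to the stroke volume.
    """
    t = np.asarray(t_ms, dtype=float)
    if np.any(t < 0) or np.any(t >= params.cycle_ms):
        raise ValueError("t must lie within [0, cycle length)")
    ed = params.ejection_duration
    frac = params.tau / ed
    a = _INFLOW_KAPPA * frac
    b = _INFLOW_KAPPA * (1.0 - frac)
    sv = params.stroke_volume  # ml
    ed_s = ed / 1000.0
    q0 = sv / (ed_s * beta_fn(a + 1.0, b + 1.0))
    s = np.clip(t / ed, 0.0, 1.0)
    with np.errstate(invalid="ignore"):
        q = np.where((s > 0) & (s < 1), q0 * s**a * (1.0 - s) ** b, 0.0)
    return float(q) if q.ndim == 0 else q


@dataclass(frozen=True)
class NumericsConfig:
    dx_cm: float = 0.25
    cfl: float = 0.9
    tol_mmhg: float = 0.5
    max_cycles: int = 20
    output_dt_ms: float = 1.0
    junction_mode: str = "pressure"
    fixed_cycles: int | None = None  # run exactly this many cycles (smooth
    # dependence on parameters; no residual-based stopping)

    def __post_init__(self):
        if self.dx_cm <= 0 or not 0 < self.cfl <= 1 or self.tol_mmhg <= 0:
            raise ValueError("invalid numerics configuration")
        if self.junction_mode != "pressure":
            raise ValueError(
                "only continuity of static pressure is implemented "
                "for junction coupling"
            )


class _CompiledTree:
    """Flat-array discretisation of a tree for the solver kernel."""

    def __init__(self, tree: ArterialTree, params: PatientParameters,
                 constants: HemoConstants, config: NumericsConfig):
        wall = params.wall
        order = []
        stack = [tree.root]
        while stack:
            vid = stack.pop()
            order.append(vid)
            stack.extend(reversed(tree.vessels[vid].daughters))
        self.order = order
        self.index = {vid: k for k, vid in enumerate(order)}
        nv = len(order)
        vstart = np.zeros(nv, dtype=np.int64)
        vlen = np.zeros(nv, dtype=np.int64)
        vdx = np.zeros(nv)
        pos = 0
        for k, vid in enumerate(order):
            v = tree.vessels[vid]
            n = max(2, int(round(v.length / config.dx_cm)) + 1)
            vstart[k] = pos
            vlen[k] = n
            vdx[k] = v.length / (n - 1)
            pos += n
        N = pos
        r0 = np.empty(N)
        dr0dx = np.empty(N)
        for k, vid in enumerate(order):
            v = tree.vessels[vid]
            s, n = vstart[k], vlen[k]
            x = np.linspace(0.0, v.length, n)
            r0[s:s + n] = v.r0(x)
            dr0dx[s:s + n] = (v.r_out - v.r_in) / v.length
        rho = constants.rho
        F = wall_stiffness(r0, wall)
        dFdr0 = -(4.0 / 3.0) * wall.k1 * wall.k2 * np.exp(-wall.k2 * r0)
        dFdx = dFdr0 * dr0dx
        A0 = np.pi * r0**2
        dsA0dx = math.sqrt(math.pi) * dr0dx
        gamma = F * np.sqrt(A0) / rho
        cc = np.sqrt(gamma / 2.0)
        # interface-averaged coefficients (index = left node of the interface)
        A0h = np.empty(N)
        Fh = np.empty(N)
        gammah = np.empty(N)
        dFdxh = np.empty(N)
        dsA0dxh = np.empty(N)
        for k in range(nv):
            s, e = vstart[k], vstart[k] + vlen[k] - 1
            for arr, h in ((A0, A0h), (F, Fh), (gamma, gammah),
                           (dFdx, dFdxh), (dsA0dx, dsA0dxh)):
                h[s:e] = 0.5 * (arr[s:e] + arr[s + 1:e + 1])
                h[e] = arr[e]
        jn_pe, jn_d1, jn_d2 = [], [], []
        jn_vp, jn_vd1, jn_vd2, term_v = [], [], [], []
        term_node, R1, R2, Cap, p_out_c, term_vid = [], [], [], [], [], []
        for k, vid in enumerate(order):
            v = tree.vessels[vid]
            if v.terminal:
                if v.windkessel is None:
                    raise SimulationError(
                        f"terminal vessel {vid} lacks Windkessel data"
                    )
                wk = v.windkessel
                sr = 1.0 if getattr(v, "wk_fixed", False) else params.S_R
                sc = 1.0 if getattr(v, "wk_fixed", False) else params.S_C
                term_node.append(vstart[k] + vlen[k] - 1)
                term_v.append(k)
                term_vid.append(vid)
                R1.append(wk.R1 * sr)
                R2.append(wk.R2 * sr)
                Cap.append(wk.C * sc)
                p_out_c.append(tree.p_out * MMHG_TO_CGS)
            else:
                jn_pe.append(vstart[k] + vlen[k] - 1)
                jn_vp.append(k)
                d1, d2 = v.daughters
                jn_d1.append(vstart[self.index[d1]])
                jn_d2.append(vstart[self.index[d2]])
                jn_vd1.append(self.index[d1])
                jn_vd2.append(self.index[d2])
        self.N = N
        self.vstart, self.vlen, self.vdx = vstart, vlen, vdx
        self.sqA0, self.sqA0h = np.sqrt(A0), np.sqrt(A0h)
        self.A0, self.F, self.gamma, self.cc = A0, F, gamma, cc
        self.dFdx, self.dsA0dx = dFdx, dsA0dx
        self.A0h, self.Fh, self.gammah = A0h, Fh, gammah
        self.dFdxh, self.dsA0dxh = dFdxh, dsA0dxh
        self.jn = (np.asarray(jn_pe, dtype=np.int64),
                   np.asarray(jn_d1, dtype=np.int64),
                   np.asarray(jn_d2, dtype=np.int64),
                   np.asarray(jn_vp, dtype=np.int64),
                   np.asarray(jn_vd1, dtype=np.int64),
                   np.asarray(jn_vd2, dtype=np.int64))
        self.term_node = np.asarray(term_node, dtype=np.int64)
        self.term_v = np.asarray(term_v, dtype=np.int64)
        self.term_vid = term_vid
        self.R1 = np.asarray(R1)
        self.R2 = np.asarray(R2)
        self.Cap = np.asarray(Cap)
        self.p_out_c = np.asarray(p_out_c)
        self.inlet_node = int(vstart[0])
        self.prefc = 97.0 * MMHG_TO_CGS
        self.rho = rho
        self.cf = constants.friction_coefficient
        # resting mean pressure estimate for fast initialisation
        G = 1.0 / (self.R1 + self.R2)
        self.R_parallel = 1.0 / G.sum()

    def equilibrium_state(self, params: PatientParameters):
        co = params.CO * LMIN_TO_CGS
        p_init = self.p_out_c.mean() + co * self.R_parallel
        z = 1.0 - (p_init - self.prefc) / self.F
        A = self.A0 / z**2
        q = np.zeros(self.N)
        pc = np.full(len(self.term_node), p_init)
        return A, q, pc


@dataclass
class SimulationResult:
    """One converged (or single) cycle of space-time fields on the tree.

    ``p``, ``q``, ``A`` have shape (n_times, n_nodes) over the flat node
    layout of the compiled tree; use :meth:`site_series` for per-site
    waveforms in clinical units.
    """

    time_ms: np.ndarray
    p: np.ndarray  # mmHg
    q: np.ndarray  # cm^3/s
    A: np.ndarray  # cm^2
    compiled: "_CompiledTree"
    tree: ArterialTree
    params: PatientParameters
    cycles_run: int = 1
    residual_mmhg: float = float("nan")
    inflow_volume: float = 0.0  # cm^3 over the cycle
    outflow_volume: float = 0.0
    volume_change: float = 0.0  # stored arterial volume change over the cycle

    def _node_of(self, site) -> tuple[int, int, float]:
        vid, frac = self.tree.site(site)
        k = self.compiled.index[vid]
        s, n = self.compiled.vstart[k], self.compiled.vlen[k]
        pos = frac * (n - 1)
        i = int(min(n - 2, math.floor(pos)))
        return s + i, s + i + 1, pos - i

    def site_series(self, site):
        """(time_ms, p_mmHg, q_ml_s) at a named site or (vessel id, fraction)."""
        i, j, w = self._node_of(site)
        p = (1 - w) * self.p[:, i] + w * self.p[:, j]
        q = (1 - w) * self.q[:, i] + w * self.q[:, j]
        return self.time_ms, p, q

    def vessel_fields(self, vid: int):
        """(x_cm, p, q, A) space-time grids for one vessel."""
        k = self.compiled.index[vid]
        s, n = self.compiled.vstart[k], self.compiled.vlen[k]
        x = np.arange(n) * self.compiled.vdx[k]
        sl = slice(s, s + n)
        return x, self.p[:, sl], self.q[:, sl], self.A[:, sl]

    @property
    def volume_balance_residual(self) -> float:
        """|inflow - outflow - storage change| over the cycle, in cm^3."""
        return abs(self.inflow_volume - self.outflow_volume - self.volume_change)


def _total_volume(compiled: _CompiledTree, A: np.ndarray) -> float:
    vol = 0.0
    for k in range(len(compiled.vstart)):
        s, n = compiled.vstart[k], compiled.vlen[k]
        vol += np.trapezoid(A[s:s + n], dx=compiled.vdx[k])
    return vol


def _run_cycle(compiled, params, config, state):
    A, q, pc = state
    T = params.cycle_ms / 1000.0
    c0 = compiled.cc * compiled.A0**-0.25
    vmax = float(np.max(c0)) * 1.1 + 150.0
    dt_cfl = config.cfl * float(np.min(compiled.vdx)) / vmax
    rec_dt = config.output_dt_ms / 1000.0
    rec_every = max(1, int(math.ceil(rec_dt / dt_cfl)))
    nrec = max(2, int(round(T / (rec_every * dt_cfl))))
    nsteps = nrec * rec_every
    dt = T / nsteps
    tgrid = np.arange(nsteps + 1) * dt * 1000.0
    t_in = np.where(tgrid >= params.cycle_ms, 0.0, tgrid)
    qin = inflow_profile(t_in, params)
    th = (np.arange(nsteps) + 0.5) * dt * 1000.0
    qinh = inflow_profile(np.where(th >= params.cycle_ms, 0.0, th), params)
    recA = np.empty((nrec + 1, compiled.N))
    recq = np.empty((nrec + 1, compiled.N))
    v_before = _total_volume(compiled, A)
    status, vin, vout = _kernel.run_cycle(
        A, q, pc, nsteps, dt,
        compiled.A0, compiled.sqA0, compiled.F, compiled.gamma, compiled.cc,
        compiled.dFdx, compiled.dsA0dx,
        compiled.A0h, compiled.sqA0h, compiled.Fh, compiled.gammah,
        compiled.dFdxh, compiled.dsA0dxh,
        compiled.rho, compiled.prefc, compiled.cf,
        compiled.vstart, compiled.vlen, compiled.vdx,
        compiled.jn[0], compiled.jn[1], compiled.jn[2],
        compiled.jn[3], compiled.jn[4], compiled.jn[5],
        compiled.term_node, compiled.term_v,
        compiled.R1, compiled.R2, compiled.Cap,
        compiled.p_out_c, compiled.inlet_node, qin, qinh,
        rec_every, recA, recq)
    if status == _kernel.STATUS_NEG_AREA:
        raise SimulationError(
            "negative cross-sectional area encountered (numerical instability); "
            "try a smaller dx/CFL or check parameter magnitudes"
        )
    v_after = _total_volume(compiled, A)
    time_ms = np.arange(nrec + 1) * rec_every * dt * 1000.0
    p = (compiled.prefc
         + compiled.F * (1.0 - np.sqrt(compiled.A0 / recA))) / MMHG_TO_CGS
    return SimulationResult(
        time_ms=time_ms, p=p, q=recq, A=recA,
        compiled=compiled, tree=None, params=params,
        inflow_volume=vin, outflow_volume=vout,
        volume_change=v_after - v_before,
    ), (A, q, pc)


def simulate_cycle(tree: ArterialTree, params: PatientParameters,
                   constants: HemoConstants | None = None,
                   config: NumericsConfig | None = None,
                   state=None) -> SimulationResult:
    """Simulate a single cardiac cycle (from equilibrium unless ``state`` given)."""
    constants = constants or HemoConstants()
    config = config or NumericsConfig()
    compiled = _CompiledTree(tree, params, constants, config)
    if state is None:
        state = compiled.equilibrium_state(params)
    result, _ = _run_cycle(compiled, params, config, state)
    result.tree = tree
    return result


def converge_to_periodic(tree: ArterialTree, params: PatientParameters,
                         constants: HemoConstants | None = None,
                         config: NumericsConfig | None = None,
                         tol: float | None = None,
                         max_cycles: int | None = None,
                         state0=None) -> SimulationResult:
    """Repeat cycles until the root pressure trace is cycle-to-cycle periodic.

    Stops when the max-norm difference of consecutive root pressure traces
    drops below ``tol`` (mmHg); raises :class:`ConvergenceError` carrying the
    residual trace otherwise.
    """
    constants = constants or HemoConstants()
    config = config or NumericsConfig()
    tol = tol if tol is not None else config.tol_mmhg
    if tol <= 0:
        raise ValueError("tol must be positive")
    max_cycles = max_cycles if max_cycles is not None else config.max_cycles
    compiled = _CompiledTree(tree, params, constants, config)
    if state0 is not None:
        A, q, pc = state0
        if A.shape[0] != compiled.N:
            raise ValueError("state0 does not match the tree discretisation")
        state = (A.copy(), q.copy(), pc.copy())
    else:
        state = compiled.equilibrium_state(params)
    prev_root = None
    residuals = []
    n_cycles = config.fixed_cycles or max_cycles
    for cycle in range(1, n_cycles + 1):
        result, state = _run_cycle(compiled, params, config, state)
        root = result.p[:, compiled.inlet_node]
        if prev_root is not None:
            res = float(np.max(np.abs(root - prev_root)))
            residuals.append(res)
            if config.fixed_cycles is None and res < tol:
                result.tree = tree
                result.cycles_run = cycle
                result.residual_mmhg = res
                return result
        prev_root = root
    if config.fixed_cycles is not None:
        result.tree = tree
        result.cycles_run = n_cycles
        result.residual_mmhg = residuals[-1] if residuals else float("nan")
        return result
    raise ConvergenceError(
        f"no periodic state within {max_cycles} cycles "
        f"(last residual {residuals[-1]:.3g} mmHg)", residuals)
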