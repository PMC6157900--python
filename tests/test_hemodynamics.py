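import numpy as np
import pytest

from pulsewave.hemodynamics import (
    ConvergenceError,
    NumericsConfig,
    PatientParameters,
    WindkesselBC,
    converge_to_periodic,
    inflow_profile,
    simulate_cycle,
    windkessel_step,
)
from pulsewave.units import MMHG_TO_CGS

from conftest import HD_MEAN_KW, uniform_tube


class TestPatientParameters:
    def test_stroke_volume_from_printed_means(self):
        p = PatientParameters(**HD_MEAN_KW, HR=60)
        assert p.stroke_volume == pytest.approx(3.56 * 1000 / 60, rel=1e-12)
        assert p.stroke_volume == pytest.approx(59.3, abs=0.05)

    def test_tau_must_precede_ejection_end(self):
        with pytest.raises(ValueError):
            PatientParameters(k1=1e7, k3=1e6, CO=4.0, tau=400.0,
                              S_R=1.0, S_C=10.0, HR=70, ED=300.0)


class TestInflowProfile:
    def test_integral_equals_stroke_volume(self):
        p = PatientParameters(**HD_MEAN_KW, HR=60)
        t = np.linspace(0, p.cycle_ms, 200001)[:-1]
        q = inflow_profile(t, p)
        sv = np.trapezoid(q, t / 1000.0)
        assert sv == pytest.approx(p.stroke_volume, rel=1e-6)

    def test_zero_in_diastole(self):
        p = PatientParameters(**HD_MEAN_KW, HR=60, ED=300.0)
        assert inflow_profile(300.1, p) == 0.0
        assert inflow_profile(900.0, p) == 0.0

    def test_single_maximum_at_tau(self):
        p = PatientParameters(**HD_MEAN_KW, HR=60, ED=330.0)
        t = np.linspace(0, 999.9, 100000)
        q = inflow_profile(t, p)
        assert t[np.argmax(q)] == pytest.approx(p.tau, abs=0.05)
        interior = q[(t > 0) & (t < 330)]
        d = np.sign(np.diff(interior))
        # rises then falls exactly once
        assert np.sum(np.diff(d) != 0) == 1

    def test_nonnegative(self):
        p = PatientParameters(**HD_MEAN_KW, HR=70)
        t = np.linspace(0, p.cycle_ms * 0.999, 5000)
        assert np.all(inflow_profile(t, p) >= 0)


class TestWindkessel:
    def test_decay_to_venous_pressure(self):
        bc = WindkesselBC(R1=1e3, R2=1e4, C=1e-4, p_out=5.0)
        p_c = 100.0 * MMHG_TO_CGS
        for _ in range(1000):
            _, p_c = windkessel_step(p_c, 0.0, bc, 0.05)
        assert p_c == pytest.approx(5.0 * MMHG_TO_CGS, rel=1e-6)

    def test_constant_inflow_steady_state(self):
        bc = WindkesselBC(R1=1e3, R2=1e4, C=1e-4, p_out=0.0)
        p_c = 0.0
        for _ in range(2000):
            p_T, p_c = windkessel_step(p_c, 1.0, bc, 0.01)
        assert p_T == pytest.approx(1.1e4, rel=1e-6)  # q (R1 + R2)

    def test_exponential_relaxation_rate(self):
        bc = WindkesselBC(R1=1e3, R2=1e4, C=1e-4, p_out=0.0)
        tau = bc.R2 * bc.C  # 1 s
        p_c = 0.0
        t, dt = 0.0, 0.01
        while t < 5 * tau - 1e-9:
            _, p_c = windkessel_step(p_c, 1.0, bc, dt)
            t += dt
        assert p_c == pytest.approx(1e4, rel=0.01)  # within 1% after 5 tau

    def test_invalid_dt(self):
        bc = WindkesselBC(R1=1.0, R2=1.0, C=1.0)
        with pytest.raises(ValueError):
            windkessel_step(0.0, 0.0, bc, 0.0)


class TestSolver:
    def test_zero_inflow_equilibrium(self):
        tube = uniform_tube(p_out=50.0)
        p = PatientParameters(**{**HD_MEAN_KW, "CO": 0.0}, HR=60)
        res = simulate_cycle(tube, p, config=NumericsConfig(dx_cm=0.5))
        # fields stay at the uniform venous state over the whole cycle
        assert np.max(np.abs(res.p - 50.0)) < 0.5
        assert np.max(np.abs(res.q)) < 0.05

    def test_volume_conservation_coarse(self, tree, hd_mean_params):
        res = converge_to_periodic(tree, hd_mean_params,
                                   config=NumericsConfig(dx_cm=1.0))
        sv = hd_mean_params.stroke_volume
        assert res.volume_balance_residual / sv < 0.005

    def test_bifurcation_flow_and_pressure_coupling(self, hd_mean_sim):
        c = hd_mean_sim.compiled
        for pe, d1, d2 in zip(c.jn[0], c.jn[1], c.jn[2]):
            q_mismatch = hd_mean_sim.q[:, pe] - (
                hd_mean_sim.q[:, d1] + hd_mean_sim.q[:, d2])
            assert np.max(np.abs(q_mismatch)) < 1e-9
            assert np.max(np.abs(
                hd_mean_sim.p[:, pe] - hd_mean_sim.p[:, d1])) < 1e-6
            assert np.max(np.abs(
                hd_mean_sim.p[:, pe] - hd_mean_sim.p[:, d2])) < 1e-6

    def test_reference_area_maps_to_reference_pressure(self, hd_mean_sim):
        c = hd_mean_sim.compiled
        # wherever the solution crosses A0, the tube law must give 97 mmHg
        k = c.N // 2
        A = hd_mean_sim.A[:, k]
        p = hd_mean_sim.p[:, k]
        j = int(np.argmin(np.abs(A - c.A0[k])))
        # interpolate pressure at exactly A0
        assert np.interp(c.A0[k], np.sort(A),
                         p[np.argsort(A)]) == pytest.approx(97.0, abs=1.5)

    def test_convergence_metadata_and_tol_monotonicity(self, tree,
                                                       hd_mean_params):
        cfg = NumericsConfig(dx_cm=1.0)
        res_loose = converge_to_periodic(tree, hd_mean_params, config=cfg,
                                         tol=2.0)
        res_tight = converge_to_periodic(tree, hd_mean_params, config=cfg,
                                         tol=0.5)
        assert res_tight.cycles_run >= res_loose.cycles_run
        assert res_tight.residual_mmhg < 0.5
        assert res_tight.cycles_run <= 10

    def test_nonconvergence_raises_with_residuals(self, tree,
                                                  hd_mean_params):
        with pytest.raises(ConvergenceError) as err:
            converge_to_periodic(tree, hd_mean_params,
                                 config=NumericsConfig(dx_cm=1.0),
                                 tol=1e-6, max_cycles=3)
        assert len(err.value.residuals) > 0

    def test_grid_convergence_radial_site(self, tree, hd_mean_params):
        cfgs = [NumericsConfig(dx_cm=1.0, output_dt_ms=1.0),
                NumericsConfig(dx_cm=0.5, output_dt_ms=1.0)]
        traces = []
        for cfg in cfgs:
            res = converge_to_periodic(tree, hd_mean_params, config=cfg)
            t, p, _ = res.site_series("radial_distal")
            traces.append((t, p))
        p_interp = np.interp(traces[1][0], traces[0][0], traces[0][1])
        assert np.max(np.abs(p_interp - traces[1][1])) < 1.0

    def test_stiffer_tree_increases_pwv(self, tree, hd_mean_params):
        from pulsewave.waveform_analysis import pulse_wave_velocity

        cfg = NumericsConfig(dx_cm=1.0, output_dt_ms=0.5)
        base = converge_to_periodic(tree, hd_mean_params, config=cfg)
        stiff_kw = {**HD_MEAN_KW, "k1": 2 * HD_MEAN_KW["k1"],
                    "k3": 2 * HD_MEAN_KW["k3"]}
        stiff = PatientParameters(**stiff_kw, HR=70, height=170,
                                  brachial_SP=120, brachial_DP=80)
        res2 = converge_to_periodic(tree, stiff, config=cfg)
        pwv1 = pulse_wave_velocity(base, "aortic_arch", "femoral")
        pwv2 = pulse_wave_velocity(res2, "aortic_arch", "femoral")
        assert pwv2 > pwv1

    def test_fixed_cycles_mode(self, tree, hd_mean_params):
        cfg = NumericsConfig(dx_cm=1.0, fixed_cycles=4)
        res = converge_to_periodic(tree, hd_mean_params, config=cfg)
        assert res.cycles_run == 4
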