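"""Integration engine: determinism, batching, convergence, voltage clamp."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from slowswitch.analysis import detect_spikes
from slowswitch.engine import integrate, integrate_batch, voltage_clamp
from slowswitch.ionic import (
    NeuronParams,
    NeuronState,
    equilibrium_gating,
    state_derivative,
    total_ionic_current,
)
from slowswitch.network import build_network, reference_circuit
from slowswitch.protocols import StimulusProtocol


def isolated_cell(seed=0, cat_mode="slow"):
    spec = build_network(1, 1, seed=seed, cat_mode=cat_mode)
    spec.W_ampa[:] = 0.0
    spec.W_gaba_a[:] = 0.0
    spec.W_gaba_b[:] = 0.0
    return spec


class TestBatchingAndDeterminism:
    def test_batch_of_one_equals_single_integrate(self):
        spec = build_network(2, 2, seed=1)
        proto = StimulusProtocol().step(100, 300, -2.6, target="I")
        a = integrate(spec, proto, t_end=500.0)
        [b] = integrate_batch([spec], proto, t_end=500.0)
        np.testing.assert_array_equal(a.V, b.V)
        for sa, sb in zip(a.spikes, b.spikes):
            np.testing.assert_array_equal(sa, sb)

    def test_identical_specs_give_identical_batch_members(self):
        spec = build_network(1, 1, seed=2)
        res = integrate_batch([spec] * 5, None, t_end=400.0)
        for r in res[1:]:
            np.testing.assert_array_equal(res[0].V, r.V)

    def test_rerun_is_bit_identical(self):
        spec = build_network(3, 3, seed=3)
        a = integrate(spec, None, t_end=300.0)
        b = integrate(spec, None, t_end=300.0)
        np.testing.assert_array_equal(a.V, b.V)

    def test_mixed_topology_batch_rejected(self):
        with pytest.raises(ValueError):
            integrate_batch([build_network(1, 1, seed=0), build_network(2, 1, seed=0)])

    def test_invalid_dt_rejected(self):
        with pytest.raises(ValueError):
            integrate(build_network(1, 1, seed=0), None, t_end=10.0, dt=0.0)


class TestTrajectoryQuality:
    def test_holds_an_equilibrium_found_by_root_finding(self):
        """Starting exactly at a stable equilibrium, the trajectory stays
        within solver tolerance of it."""
        spec = isolated_cell(seed=0)
        p = NeuronParams.central()
        for name in ("g_leak", "g_Na", "g_Kd", "g_CaT", "g_KCa", "g_H", "k1", "k2"):
            np.asarray(getattr(spec.params, name))[:] = getattr(p, name)
        i_app = -2.6

        def f(v):
            return float(-total_ionic_current(p, equilibrium_gating(p, v)) + i_app)

        grid = np.linspace(-110.0, -70.0, 81)
        fv = [f(v) for v in grid]
        (idx,) = np.nonzero(np.diff(np.sign(fv)))
        v_eq = brentq(f, grid[idx[0]], grid[idx[0] + 1], xtol=1e-12)

        proto = StimulusProtocol().step(0.0, 1000.0, i_app, target="all")
        res = integrate(spec, proto, t_end=1000.0, V0=v_eq)
        assert np.max(np.abs(res.V[0] - v_eq)) < 0.5

    def test_matches_adaptive_high_accuracy_integrator_before_first_spike(self):
        """Fixed-step trajectory tracks an independent adaptive integrator to
        within 0.5 mV up to the first spike upstroke."""
        p = NeuronParams.central()
        names = ["V", "m_Na", "h_Na", "m_Kd", "m_CaT", "h_CaT", "m_H", "Ca"]
        # release from a hyperpolarized hold: the slow T-type rebound gives a
        # long, dynamically rich sub-threshold stretch before the first spike
        st0 = equilibrium_gating(p, -90.0)
        y0 = [float(np.asarray(getattr(st0, n))) for n in names]

        def rhs(t, y):
            st = NeuronState(**dict(zip(names, y)))
            d = state_derivative(p, st)
            return [d[n] for n in names]

        t_end = 400.0
        sol = solve_ivp(rhs, (0.0, t_end), y0, method="LSODA",
                        rtol=1e-10, atol=1e-12, dense_output=True)
        spec = isolated_cell(seed=0)
        for name in ("g_leak", "g_Na", "g_Kd", "g_CaT", "g_KCa", "g_H", "k1", "k2"):
            np.asarray(getattr(spec.params, name))[:] = getattr(p, name)
        res = integrate(spec, None, t_end=t_end, V0=-90.0)
        v_ref = sol.sol(res.t)[0]
        # compare up to just before the upstroke of the first spike
        upstroke = np.nonzero(v_ref > -40.0)[0]
        stop = upstroke[0] - 2 if upstroke.size else len(v_ref)
        assert stop > 10
        assert np.max(np.abs(res.V[0][:stop] - v_ref[:stop])) < 0.5

    def test_observables_converge_under_dt_halving(self):
        """Two-cell reference circuit under the switch step: halving dt
        preserves spike counts and moves early spikes by under a
        millisecond.  Late spike times in the coupled rebound rhythm are
        exponentially sensitive to the trajectory, so the convergence
        statement is about observables, not pointwise times."""
        spec = reference_circuit()
        proto = StimulusProtocol().step(500, 2000, -2.6, target="I")
        a = integrate(spec, proto, t_end=2000.0, dt=0.05, record_v=False)
        b = integrate(spec, proto, t_end=2000.0, dt=0.025, record_v=False)
        for sa, sb in zip(a.spikes, b.spikes):
            sa, sb = np.asarray(sa), np.asarray(sb)
            assert abs(len(sa) - len(sb)) <= max(1, 0.05 * len(sa))
            # first spike converges pointwise; the rhythm converges in rate
            assert abs(sa[0] - sb[0]) < 1.0
            if len(sa) > 5 and len(sb) > 5:
                isi_a = np.mean(np.diff(sa))
                isi_b = np.mean(np.diff(sb))
                assert isi_a == pytest.approx(isi_b, rel=0.02)

    def test_gating_and_calcium_stay_in_bounds(self):
        spec = build_network(2, 2, seed=5)
        proto = StimulusProtocol().step(500, 2500, -2.6, target="I")
        res = integrate(spec, proto, t_end=3000.0, record_v=False)
        lo, hi = res.meta["gating_bounds"]
        assert lo >= 0.0 and hi <= 1.0
        assert res.meta["ca_min"] >= 0.0

    def test_online_spike_detection_agrees_with_trace_detector(self):
        spec = isolated_cell(seed=1)
        res = integrate(spec, None, t_end=2000.0)
        offline = detect_spikes(res.V[0], res.t[1] - res.t[0])
        online = np.asarray(res.spikes[0])
        assert len(offline) == len(online)
        if len(online):
            assert np.max(np.abs(offline - online)) <= 1.5


class TestVoltageClamp:
    SCHED_60 = [(0.0, 1000.0, -60.0), (1000.0, 2500.0, -35.0)]
    SCHED_90 = [(0.0, 1000.0, -90.0), (1000.0, 2500.0, -35.0)]

    def test_from_minus_60_models_agree_far_better_than_from_minus_90(self):
        """From -60 mV the T channels are inactivated and the two activation
        models respond near-identically; from -90 mV (deinactivated) they
        diverge by an order of magnitude more."""
        p = NeuronParams.central()
        d60 = np.abs(
            voltage_clamp(p, self.SCHED_60)["I_total"]
            - voltage_clamp(p.with_mode("instantaneous"), self.SCHED_60)["I_total"]
        ).max()
        d90 = np.abs(
            voltage_clamp(p, self.SCHED_90)["I_total"]
            - voltage_clamp(p.with_mode("instantaneous"), self.SCHED_90)["I_total"]
        ).max()
        assert d60 < 0.1 * d90

    def test_from_minus_90_slow_model_has_a_distinct_slow_phase(self):
        p = NeuronParams.central()
        a = voltage_clamp(p, self.SCHED_90)
        b = voltage_clamp(p.with_mode("instantaneous"), self.SCHED_90)
        t = a["t"]
        win = (t >= 1000.0) & (t < 1400.0)
        # time for each model's T-current to reach half its peak magnitude
        def t_half(out):
            i_cat = out["currents"]["CaT"][win]
            peak = np.min(i_cat)
            return t[win][np.nonzero(i_cat <= peak / 2)[0][0]] - 1000.0

        assert t_half(a) > 5 * t_half(b)

    def test_same_steady_state_current_after_the_step(self):
        p = NeuronParams.central()
        sched = [(0.0, 1000.0, -90.0), (1000.0, 6000.0, -35.0)]
        a = voltage_clamp(p, sched)
        b = voltage_clamp(p.with_mode("instantaneous"), sched)
        assert a["I_total"][-1] == pytest.approx(b["I_total"][-1], rel=1e-6, abs=1e-6)
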