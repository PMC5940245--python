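"""Gating curves, ionic currents and the neuron state derivative."""

import numpy as np
import pytest
from scipy.optimize import brentq

from slowswitch.ionic import (
    GATING,
    PARAM_RANGES,
    NeuronParams,
    NeuronState,
    equilibrium_gating,
    initial_state,
    ionic_currents,
    m_kca,
    state_derivative,
    steady_state,
    steady_state_current,
    tau_h_na,
    time_constant,
    total_ionic_current,
)


class TestGatingCurves:
    def test_steady_state_half_activation_at_v_half(self):
        for spec in GATING.values():
            assert steady_state(spec, spec.v_half) == pytest.approx(0.5)

    def test_steady_state_matches_direct_formula(self):
        # independent scalar evaluation at an arbitrary potential
        spec = GATING["m_CaT"]
        v = -60.0
        expected = 1.0 / (1.0 + np.exp((v - (-67.1)) / (-7.2)))
        assert steady_state(spec, v) == pytest.approx(expected, rel=1e-15)
        assert expected == pytest.approx(0.72832, abs=5e-6)

    def test_inactivation_limits(self):
        # positive v_slope => inactivation: 1 at -inf, 0 at +inf
        h = GATING["h_Na"]
        assert steady_state(h, 200.0) < 1e-10
        assert steady_state(h, -200.0) > 1.0 - 1e-10

    @pytest.mark.parametrize(
        "name, v, expected",
        [
            # at V = D the tau sigmoid is exactly 1/2: tau = A - B/2
            ("m_CaT", -68.1, 21.7 - 21.3 / 2),
            ("m_Na", -120.0, 1.32 - 1.26 / 2),
            ("m_H", -42.2, 272.0 + 1149.0 / 2),
        ],
    )
    def test_time_constant_midpoint_identity(self, name, v, expected):
        assert time_constant(GATING[name], v) == pytest.approx(expected, rel=1e-12)

    def test_time_constant_positive_over_physiological_range(self):
        v = np.linspace(-120.0, 60.0, 1801)
        for name, spec in GATING.items():
            tau = tau_h_na(v) if name == "h_Na" else time_constant(spec, v)
            assert np.all(tau > 0.0), name

    def test_time_constant_rejects_h_na(self):
        with pytest.raises(ValueError):
            time_constant(GATING["h_Na"], -60.0)

    def test_tau_h_na_value_and_limits(self):
        # independent evaluation at the first sigmoid's midpoint
        expected = 0.335 * (1.5 + 1.0 / (1.0 + np.exp(-28.0 / 3.6)))
        assert tau_h_na(-62.9) == pytest.approx(expected, rel=1e-12)
        assert tau_h_na(-300.0) < 1e-8
        assert tau_h_na(300.0) == pytest.approx(0.67 * 1.5, rel=1e-9)

    def test_steady_state_monotone_direction_follows_slope_sign(self):
        v = np.linspace(-120, 60, 500)
        for spec in GATING.values():
            dx = np.diff(steady_state(spec, v))
            if spec.v_slope < 0:
                assert np.all(dx > 0), spec.name
            else:
                assert np.all(dx < 0), spec.name


class TestKCaActivation:
    def test_anchor_values(self):
        assert m_kca(0.0, 170.0) == 0.0
        assert m_kca(170.0, 170.0) == pytest.approx(0.25)
        assert m_kca(1e9, 170.0) == pytest.approx(1.0, abs=1e-6)

    def test_monotone_increasing_in_ca(self):
        ca = np.linspace(0, 500, 200)
        assert np.all(np.diff(m_kca(ca, 170.0)) > 0)


def _random_state(rng):
    return NeuronState(
        V=rng.uniform(-90, 0),
        m_Na=rng.uniform(0, 1),
        h_Na=rng.uniform(0, 1),
        m_Kd=rng.uniform(0, 1),
        m_CaT=rng.uniform(0, 1),
        h_CaT=rng.uniform(0, 1),
        m_H=rng.uniform(0, 1),
        Ca=rng.uniform(0, 100),
    )


class TestIonicCurrents:
    def test_zero_driving_force_nulls_each_current(self):
        p = NeuronParams.central()
        rng = np.random.default_rng(0)
        st = _random_state(rng)
        st.V = p.V_Na
        assert ionic_currents(p, st)["Na"] == pytest.approx(0.0)
        st.V = p.V_leak
        assert ionic_currents(p, st)["leak"] == pytest.approx(0.0)

    def test_all_gates_closed_at_leak_reversal_gives_zero_total(self):
        p = NeuronParams.central()
        st = NeuronState(V=-59.0, m_Na=0, h_Na=0, m_Kd=0, m_CaT=0, h_CaT=0, m_H=0, Ca=0)
        for name, val in ionic_currents(p, st).items():
            assert val == pytest.approx(0.0), name

    def test_matches_literal_transcription(self):
        """Cross-check against an independent literal evaluation of the
        current definitions, to near machine precision."""
        rng = np.random.default_rng(42)
        for _ in range(20):
            draws = {k: rng.uniform(lo, hi) for k, (lo, hi) in PARAM_RANGES.items()}
            p = NeuronParams(**draws, K_D_ca=170.0)
            s = _random_state(rng)
            cur = ionic_currents(p, s)
            V = s.V
            ref = {
                "leak": draws["g_leak"] * (V + 59.0),
                "Na": draws["g_Na"] * s.m_Na**3 * s.h_Na * (V - 50.0),
                "Kd": draws["g_Kd"] * s.m_Kd**4 * (V + 85.0),
                "CaT": draws["g_CaT"] * s.m_CaT**3 * s.h_CaT * (V - 120.0),
                "KCa": draws["g_KCa"] * (s.Ca / (s.Ca + 170.0)) ** 2 * (V + 85.0),
                "H": draws["g_H"] * s.m_H * (V + 20.0),
            }
            for name in ref:
                assert cur[name] == pytest.approx(ref[name], rel=1e-12), name

    def test_printed_kca_reversal_variant(self):
        p = NeuronParams.central(kca_reversal="VCa")
        st = _random_state(np.random.default_rng(1))
        st.V = p.V_Ca
        assert ionic_currents(p, st)["KCa"] == pytest.approx(0.0)

    def test_instantaneous_mode_uses_steady_state_activation(self):
        p = NeuronParams.central(cat_mode="instantaneous")
        st = _random_state(np.random.default_rng(2))
        cur = ionic_currents(p, st)
        m_inf = steady_state(GATING["m_CaT"], st.V)
        expected = p.g_CaT * m_inf**3 * st.h_CaT * (st.V - p.V_Ca)
        assert cur["CaT"] == pytest.approx(expected, rel=1e-12)


class TestStateDerivative:
    def test_gating_derivative_zero_at_steady_state(self):
        p = NeuronParams.central()
        st = equilibrium_gating(p, -65.0)
        d = state_derivative(p, st)
        for name in ("m_Na", "h_Na", "m_Kd", "m_CaT", "h_CaT", "m_H"):
            assert d[name] == pytest.approx(0.0, abs=1e-14), name

    def test_ca_decay_rate_without_ca_current(self):
        p = NeuronParams.central(g_CaT=0.0)
        st = equilibrium_gating(p, -65.0)
        st.Ca = 40.0
        d = state_derivative(p, st)
        assert d["Ca"] == pytest.approx(-p.k2 * 40.0, rel=1e-12)

    def test_instantaneous_mode_drops_m_cat_from_state(self):
        p = NeuronParams.central(cat_mode="instantaneous")
        d = state_derivative(p, initial_state(p))
        assert "m_CaT" not in d
        assert "m_CaT" in state_derivative(p.with_mode("slow"), initial_state(p))

    def test_all_derivatives_vanish_at_a_root_found_independently(self):
        """Locate a voltage equilibrium with an independent root-finder and
        confirm the full state derivative vanishes there."""
        p = NeuronParams.central()
        i_app = -2.6  # hyperpolarized branch has a genuine stable equilibrium

        def f(v):
            return float(-total_ionic_current(p, equilibrium_gating(p, v)) + i_app)

        grid = np.linspace(-110.0, -60.0, 101)
        fv = np.array([f(v) for v in grid])
        (idx,) = np.nonzero(np.diff(np.sign(fv)))
        assert idx.size, "no equilibrium bracket found"
        v_eq = brentq(f, grid[idx[0]], grid[idx[0] + 1], xtol=1e-13)
        d = state_derivative(p, equilibrium_gating(p, v_eq), I_app=i_app)
        for name, val in d.items():
            assert val == pytest.approx(0.0, abs=1e-9), name


class TestSteadyStateEquivalence:
    def test_slow_and_instantaneous_share_the_iv_curve(self):
        """The activation-kinetics ablation is purely dynamical: relaxed total
        currents agree to high precision on a voltage grid."""
        rng = np.random.default_rng(7)
        v_grid = np.linspace(-90.0, 0.0, 31)
        for _ in range(25):
            draws = {k: rng.uniform(lo, hi) for k, (lo, hi) in PARAM_RANGES.items()}
            slow = NeuronParams(**draws, cat_mode="slow")
            inst = NeuronParams(**draws, cat_mode="instantaneous")
            i_s = np.array([steady_state_current(slow, v) for v in v_grid])
            i_i = np.array([steady_state_current(inst, v) for v in v_grid])
            np.testing.assert_allclose(i_s, i_i, rtol=1e-9, atol=1e-12)
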