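"""Single-compartment conductance-based neuron: gating curves, ionic currents,
calcium dynamics and the state derivative.

The neuron carries six currents — leak, transient Na, delayed-rectifier K,
T-type Ca, Ca-activated K, and the hyperpolarization-activated cation current
I_H.  Voltage-gated variables follow first-order kinetics

    tau_x(V) dx/dt = x_inf(V) - x,

with Boltzmann steady states ``x_inf(V) = 1/(1+exp((V-V_half)/V_slope))`` and
sigmoid time constants ``tau_x(V) = A - B/(1+exp((V-D)/E))``; the Na
inactivation time constant uses a dedicated bell-shaped product formula.

The T-type Ca activation kinetics are switchable: in ``slow`` mode m_CaT is a
dynamical variable with its physiological time constant (roughly ten-fold
slower than Na activation); in ``instantaneous`` mode it is evaluated as
m_CaT_inf(V) and removed from the state vector.  Both modes share the same
steady-state currents — the ablation is purely dynamical.

Units: mV, ms, uA/cm^2, mS/cm^2, uF/cm^2; intracellular Ca in uM.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Literal

import numpy as np

__all__ = [
    "GatingSpec",
    "GATING",
    "PARAM_RANGES",
    "CENTRAL_KD_CA",
    "NeuronParams",
    "NeuronState",
    "steady_state",
    "time_constant",
    "tau_h_na",
    "m_kca",
    "ionic_currents",
    "total_ionic_current",
    "state_derivative",
    "equilibrium_gating",
    "initial_state",
    "steady_state_current",
]

CatMode = Literal["slow", "instantaneous"]


@dataclass(frozen=True)
class GatingSpec:
    """Sigmoid parameters for one voltage-gated variable.

    ``v_slope < 0`` gives an activation curve (increasing with V),
    ``v_slope > 0`` an inactivation curve.  ``has_tau_table`` is False for
    h_Na, whose time constant comes from :func:`tau_h_na`.
    """

    name: str
    v_half: float
    v_slope: float
    A: float | None = None
    B: float | None = None
    D: float | None = None
    E: float | None = None

    @property
    def has_tau_table(self) -> bool:
        return self.A is not None


def _load_gating_table() -> dict[str, GatingSpec]:
    text = resources.files("slowswitch.data").joinpath("gating_table.json").read_text()
    raw = json.loads(text)
    raw.pop("comment", None)
    return {name: GatingSpec(name=name, **vals) for name, vals in raw.items()}


#: Gating-curve parameters for m_Na, h_Na, m_Kd, m_CaT, h_CaT, m_H.
GATING: dict[str, GatingSpec] = _load_gating_table()

#: Uniform sampling ranges for the randomized maximal conductances and the
#: calcium influx/removal rates (mS/cm^2 except k1, k2).  The leak range is a
#: tight +/-10% band around 0.0525: a weak leak is what lets the slow T-type
#: negative conductance dominate near rest, so cells fire tonically at
#: I_app = 0 and enter the slow bursting-prone mode under hyperpolarization
#: (see docs/methods.md on this choice).
PARAM_RANGES: dict[str, tuple[float, float]] = {
    "g_leak": (0.0475, 0.0575),
    "g_Na": (135.0, 205.0),
    "g_Kd": (20.0, 60.0),
    "g_CaT": (0.375, 0.725),
    "g_KCa": (3.0, 5.0),
    "g_H": (0.0095, 0.0105),
    "k1": (0.075, 0.125),
    "k2": (0.0075, 0.0125),
}

#: Half-activation (uM) of the Ca-activated K conductance.  Implementation
#: chosen: calibrated once, together with the central synaptic conductances,
#: so that the reference two-cell circuit shows the hyperpolarization-induced
#: switch from tonic spiking to synchronized bursting; see docs/methods.md.
CENTRAL_KD_CA: float = 250.0


@dataclass
class NeuronParams:
    """Maximal conductances, reversal potentials and Ca dynamics of one cell.

    Every conductance field may be a scalar or an ndarray (broadcast over a
    cell/ensemble axis), so a single instance can describe a whole batch of
    heterogeneous neurons.
    """

    g_leak: float | np.ndarray
    g_Na: float | np.ndarray
    g_Kd: float | np.ndarray
    g_CaT: float | np.ndarray
    g_KCa: float | np.ndarray
    g_H: float | np.ndarray
    k1: float | np.ndarray
    k2: float | np.ndarray
    K_D_ca: float | np.ndarray = CENTRAL_KD_CA
    C_m: float = 1.0
    V_Na: float = 50.0
    V_K: float = -85.0
    V_Ca: float = 120.0
    V_leak: float = -59.0
    V_H: float = -20.0
    cat_mode: CatMode = "slow"
    # The source print of I_KCa carries a (V - V_Ca) driving force, which makes
    # a Ca-activated *potassium* current depolarizing.  Default is the
    # physiological V_K reversal; the printed variant stays available.
    kca_reversal: Literal["VK", "VCa"] = "VK"

    @classmethod
    def central(cls, cat_mode: CatMode = "slow", **overrides) -> "NeuronParams":
        """Reference cell: every sampled parameter at its range midpoint."""
        mids = {k: 0.5 * (lo + hi) for k, (lo, hi) in PARAM_RANGES.items()}
        mids.update(overrides)
        return cls(cat_mode=cat_mode, **mids)

    def with_mode(self, cat_mode: CatMode) -> "NeuronParams":
        return replace(self, cat_mode=cat_mode)

    def validate(self) -> None:
        for name in ("g_leak", "g_Na", "g_Kd", "g_CaT", "g_KCa", "g_H"):
            if np.any(np.asarray(getattr(self, name)) < 0):
                raise ValueError(f"{name} must be non-negative")
        if self.C_m <= 0:
            raise ValueError("C_m must be positive")
        if np.any(np.asarray(self.k1) <= 0) or np.any(np.asarray(self.k2) <= 0):
            raise ValueError("k1, k2 must be positive")
        if np.any(np.asarray(self.K_D_ca) <= 0):
            raise ValueError("K_D_ca must be positive")


#: Gating state names integrated in slow mode, in canonical order.
STATE_GATING_SLOW = ("m_Na", "h_Na", "m_Kd", "m_CaT", "h_CaT", "m_H")
#: In instantaneous mode m_CaT is evaluated algebraically and is not a state.
STATE_GATING_INSTANT = ("m_Na", "h_Na", "m_Kd", "h_CaT", "m_H")


def gating_names(cat_mode: CatMode) -> tuple[str, ...]:
    return STATE_GATING_SLOW if cat_mode == "slow" else STATE_GATING_INSTANT


@dataclass
class NeuronState:
    """Membrane potential, gating variables and intracellular Ca.

    In instantaneous mode ``m_CaT`` is ignored (kept as NaN by convention).
    All fields broadcast like the corresponding :class:`NeuronParams`.
    """

    V: float | np.ndarray
    m_Na: float | np.ndarray
    h_Na: float | np.ndarray
    m_Kd: float | np.ndarray
    m_CaT: float | np.ndarray
    h_CaT: float | np.ndarray
    m_H: float | np.ndarray
    Ca: float | np.ndarray


def steady_state(spec: GatingSpec, V):
    """Boltzmann steady state ``1/(1+exp((V - V_half)/V_slope))``."""
    return 1.0 / (1.0 + np.exp((np.asarray(V, dtype=float) - spec.v_half) / spec.v_slope))


def time_constant(spec: GatingSpec, V):
    """Sigmoid time constant ``A - B/(1+exp((V-D)/E))`` in ms.

    h_Na has no tabulated time constant; use :func:`tau_h_na` instead.
    """
    if not spec.has_tau_table:
        raise ValueError(f"{spec.name} has no tabulated time constant; use tau_h_na")
    V = np.asarray(V, dtype=float)
    return spec.A - spec.B / (1.0 + np.exp((V - spec.D) / spec.E))


def tau_h_na(V):
    """Na inactivation time constant (ms): bell-shaped product of two sigmoids,
    ``0.67/(1+exp(-(V+62.9)/10)) * (1.5 + 1/(1+exp((V+34.9)/3.6)))``.
    """
    V = np.asarray(V, dtype=float)
    return (0.67 / (1.0 + np.exp(-(V + 62.9) / 10.0))) * (
        1.5 + 1.0 / (1.0 + np.exp((V + 34.9) / 3.6))
    )


def tau_of(name: str, V):
    """Time constant for any gating variable, dispatching h_Na's formula."""
    return tau_h_na(V) if name == "h_Na" else time_constant(GATING[name], V)


def m_kca(Ca, K_D_ca):
    """Ca-dependent activation of the K-Ca current: ``(Ca/(Ca+K_D))^2``."""
    Ca = np.asarray(Ca, dtype=float)
    frac = Ca / (Ca + K_D_ca)
    return frac * frac


def _m_cat(params: NeuronParams, state: NeuronState):
    if params.cat_mode == "instantaneous":
        return steady_state(GATING["m_CaT"], state.V)
    return state.m_CaT


def ionic_currents(params: NeuronParams, state: NeuronState) -> dict:
    """Per-area breakdown of the six ionic currents (uA/cm^2), outward positive."""
    V = state.V
    m_cat = _m_cat(params, state)
    e_kca = params.V_Ca if params.kca_reversal == "VCa" else params.V_K
    return {
        "leak": params.g_leak * (V - params.V_leak),
        "Na": params.g_Na * state.m_Na**3 * state.h_Na * (V - params.V_Na),
        "Kd": params.g_Kd * state.m_Kd**4 * (V - params.V_K),
        "CaT": params.g_CaT * m_cat**3 * state.h_CaT * (V - params.V_Ca),
        "KCa": params.g_KCa * m_kca(state.Ca, params.K_D_ca) * (V - e_kca),
        "H": params.g_H * state.m_H * (V - params.V_H),
    }


def total_ionic_current(params: NeuronParams, state: NeuronState):
    cur = ionic_currents(params, state)
    return cur["leak"] + cur["Na"] + cur["Kd"] + cur["CaT"] + cur["KCa"] + cur["H"]


def state_derivative(
    params: NeuronParams, state: NeuronState, I_app=0.0, I_syn=0.0
) -> dict:
    """Time derivative of every dynamical state variable.

    ``dV/dt = (-sum(I_ion) - I_syn + I_app)/C_m``; gating follows
    ``(x_inf - x)/tau_x``; ``dCa/dt = -k1*I_CaT - k2*Ca`` (inward Ca current is
    negative, so influx raises Ca).  In instantaneous mode the returned dict
    has no ``m_CaT`` entry.
    """
    cur = ionic_currents(params, state)
    total = cur["leak"] + cur["Na"] + cur["Kd"] + cur["CaT"] + cur["KCa"] + cur["H"]
    out = {"V": (-total - I_syn + I_app) / params.C_m}
    for name in gating_names(params.cat_mode):
        x = getattr(state, name)
        out[name] = (steady_state(GATING[name], state.V) - x) / tau_of(name, state.V)
    out["Ca"] = -params.k1 * cur["CaT"] - params.k2 * state.Ca
    return out


def equilibrium_gating(params: NeuronParams, V) -> NeuronState:
    """State with every gating variable at x_inf(V) and Ca at its fixed point."""
    g = {name: steady_state(GATING[name], V) for name in STATE_GATING_SLOW}
    probe = NeuronState(V=V, Ca=0.0, **g)
    i_cat = ionic_currents(params, probe)["CaT"]
    ca = np.maximum(-params.k1 * i_cat / params.k2, 0.0)
    return NeuronState(V=V, Ca=ca, **g)


def initial_state(params: NeuronParams, V0=-60.0) -> NeuronState:
    """Default initial condition: gating and Ca relaxed at V0."""
    return equilibrium_gating(params, np.asarray(V0, dtype=float))


def steady_state_current(params: NeuronParams, V):
    """Total ionic current after full relaxation at clamped V.

    Slow and instantaneous T-type activation modes share this I/V curve:
    the ablation only alters transient dynamics.
    """
    return total_ionic_current(params, equilibrium_gating(params, V))
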