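"""Kinetic synapse models (AMPA, GABA_A, GABA_B) and spatially clustered weights.

Each presynaptic cell carries one gating variable s per receptor type,

    ds/dt = alpha * T_m(V_pre) * (1 - s) - beta * s,

driven by the sigmoidal transmitter-release function of the presynaptic
potential.  The postsynaptic current into cell i is
``sum_j w_ij * s_j * (V_i - E_rev)`` (outward positive).  GABA_B kinetics are
roughly fifty-fold slower than GABA_A/AMPA, which is what lets GABA_B
dominance park the postsynaptic membrane near the K reversal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ReceptorKinetics",
    "AMPA",
    "GABA_A",
    "GABA_B",
    "RECEPTORS",
    "transmitter_release",
    "receptor_derivative",
    "synaptic_current",
    "gaussian_clustered_weights",
]


@dataclass(frozen=True)
class ReceptorKinetics:
    """Rise/decay rates (ms^-1) and reversal potential (mV) of one receptor."""

    name: str
    alpha: float
    beta: float
    E_rev: float

    @property
    def s_max(self) -> float:
        """Fixed point of s under saturating release (T_m = 1)."""
        return self.alpha / (self.alpha + self.beta)


AMPA = ReceptorKinetics("AMPA", alpha=1.1, beta=0.19, E_rev=0.0)
GABA_A = ReceptorKinetics("GABA_A", alpha=0.53, beta=0.19, E_rev=-70.0)   # V_Cl
GABA_B = ReceptorKinetics("GABA_B", alpha=0.016, beta=0.0047, E_rev=-85.0)  # V_K

RECEPTORS: dict[str, ReceptorKinetics] = {r.name: r for r in (AMPA, GABA_A, GABA_B)}


def transmitter_release(V_pre):
    """Sigmoidal release function ``1/(1+exp(-(V_pre-2)/5))``, half-max at +2 mV."""
    return 1.0 / (1.0 + np.exp(-(np.asarray(V_pre, dtype=float) - 2.0) / 5.0))


def receptor_derivative(kin: ReceptorKinetics, s, V_pre):
    """ds/dt for receptor gating driven by the presynaptic potential."""
    return kin.alpha * transmitter_release(V_pre) * (1.0 - np.asarray(s)) - kin.beta * np.asarray(s)


def synaptic_current(weights: np.ndarray, s: np.ndarray, V_post, E_rev):
    """Summed postsynaptic current per target cell, outward positive.

    Parameters
    ----------
    weights : (..., n_post, n_pre) array of maximal conductances (mS/cm^2).
    s : (..., n_pre) receptor gating, shared across postsynaptic targets.
    V_post : (..., n_post) postsynaptic potentials.
    E_rev : receptor reversal potential (mV).
    """
    weights = np.asarray(weights, dtype=float)
    s = np.asarray(s, dtype=float)
    if weights.shape[-1] != s.shape[-1]:
        raise ValueError(
            f"weight matrix has {weights.shape[-1]} presynaptic columns "
            f"but gating vector has {s.shape[-1]} entries"
        )
    drive = np.matmul(weights, s[..., None])[..., 0]
    return drive * (np.asarray(V_post, dtype=float) - E_rev)


def gaussian_clustered_weights(
    g_central: float | np.ndarray,
    positions_pre: np.ndarray,
    positions_post: np.ndarray,
    c: float = 0.8,
) -> np.ndarray:
    """Spatially clustered weight matrix with per-target normalization.

    The raw profile decays as ``exp(-(x_j - x_i)^2 / (2 c^2))`` with the
    pre/post positions on a common spatial axis; each postsynaptic row is then
    rescaled so its incoming total matches the unclustered all-to-all total
    ``sum_j g_central`` — clustering redistributes synaptic strength without
    changing the overall inhibitory budget per cell.

    Positions are cell coordinates in index units of the postsynaptic array
    (see the network module), so a spread constant c below 1 confines each
    cell's strong connections to its immediate spatial neighbours.
    """
    if c <= 0:
        raise ValueError("spread constant c must be positive")
    pre = np.asarray(positions_pre, dtype=float)
    post = np.asarray(positions_post, dtype=float)
    profile = np.exp(-((post[:, None] - pre[None, :]) ** 2) / (2.0 * c**2))
    g = np.broadcast_to(np.asarray(g_central, dtype=float), profile.shape)
    target_total = g.sum(axis=1, keepdims=True)
    raw = g * profile
    return raw * (target_total / raw.sum(axis=1, keepdims=True))
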