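"""Randomized heterogeneous E-I networks.

Topology is a bipartite motif: an excitatory population projecting AMPA onto
an inhibitory population, which projects GABA_A and GABA_B back.  There are no
intra-population connections.  Heterogeneity enters through (a) per-cell
maximal conductances and Ca-dynamics rates drawn uniformly from their
physiological ranges and (b) per-connection synaptic weights drawn uniformly
within +/- 1/8 of a central value.  Connectivity is all-to-all and weak;
GABA_B (or any receptor) can optionally be spatially clustered with a
normalized Gaussian profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .ionic import PARAM_RANGES, CENTRAL_KD_CA, NeuronParams, CatMode
from .synapses import gaussian_clustered_weights

__all__ = [
    "CENTRAL_G_SYN",
    "NetworkSpec",
    "sample_neuron_params",
    "build_network",
    "perturb_modulation",
]

#: Central per-cell total synaptic conductances (mS/cm^2).  Implementation
#: chosen: the values are not printed in the source model description; these
#: were calibrated once so that the central two-cell circuit switches from
#: asynchronous tonic spiking to synchronized bursting under hyperpolarization
#: of the inhibitory cell (see docs/methods.md) and are used for every
#: network size (per-connection weight = central / n_pre).
CENTRAL_G_SYN: dict[str, float] = {
    "AMPA": 0.15,
    "GABA_A": 2.5,
    "GABA_B": 0.8,
}

#: +/- fractional half-width of the uniform weight distribution around the
#: central value.
WEIGHT_JITTER = 1.0 / 8.0


def sample_neuron_params(
    rng: np.random.Generator | int,
    n: int = 1,
    cat_mode: CatMode = "slow",
    K_D_ca: float = CENTRAL_KD_CA,
) -> NeuronParams:
    """Draw n cells' conductances and Ca rates uniformly from their ranges."""
    rng = np.random.default_rng(rng)
    draws = {k: rng.uniform(lo, hi, size=n) for k, (lo, hi) in PARAM_RANGES.items()}
    return NeuronParams(cat_mode=cat_mode, K_D_ca=K_D_ca, **draws)


def _sample_weights(rng: np.random.Generator, central: float, shape) -> np.ndarray:
    lo, hi = central * (1.0 - WEIGHT_JITTER), central * (1.0 + WEIGHT_JITTER)
    return rng.uniform(lo, hi, size=shape)


@dataclass
class NetworkSpec:
    """A fully realized network: per-cell parameters plus weight matrices.

    Cells are ordered excitatory first (indices ``0..n_E-1``) then inhibitory
    (``n_E..n_E+n_I-1``).  ``params`` holds per-cell arrays of length
    ``n_E + n_I``.  Weight matrices are (n_post, n_pre): ``W_ampa`` is
    (n_I, n_E); ``W_gaba_a`` and ``W_gaba_b`` are (n_E, n_I).
    """

    n_E: int
    n_I: int
    params: NeuronParams
    W_ampa: np.ndarray
    W_gaba_a: np.ndarray
    W_gaba_b: np.ndarray
    pathways: np.ndarray          # pathway id per I cell
    seed: int | None = None
    g_syn_central: dict = field(default_factory=lambda: dict(CENTRAL_G_SYN))
    clustered: tuple = ()
    cluster_c: float = 0.8
    n_pathways: int = 1

    @property
    def n_cells(self) -> int:
        return self.n_E + self.n_I

    @property
    def e_slice(self) -> slice:
        return slice(0, self.n_E)

    @property
    def i_slice(self) -> slice:
        return slice(self.n_E, self.n_E + self.n_I)

    @property
    def cat_mode(self) -> CatMode:
        return self.params.cat_mode

    def pathway_cells(self, pathway: int) -> np.ndarray:
        """Global indices of the inhibitory cells in one modulatory pathway."""
        return self.n_E + np.nonzero(self.pathways == pathway)[0]


def _positions(n: int, n_ref: int) -> np.ndarray:
    # cell positions in index units of the reference (postsynaptic)
    # population; with equal populations this is plain 0..n-1.  Index units
    # matter: the clustering spread c ~ 0.8 confines a cell's strong
    # connections to its immediate neighbours, which is what makes
    # per-pathway spatial control of the network state possible at all.
    return np.arange(n) * (n_ref / n)


def _pathway_assignment(n_I: int, n_pathways: int) -> np.ndarray:
    # contiguous equal blocks; the last block absorbs any remainder
    block = n_I // n_pathways
    ids = np.minimum(np.arange(n_I) // max(block, 1), n_pathways - 1)
    return ids.astype(int)


def build_network(
    n_E: int,
    n_I: int,
    seed: int | np.random.SeedSequence = 0,
    cat_mode: CatMode = "slow",
    g_syn_central: dict | None = None,
    clustered: tuple = (),
    cluster_c: float = 0.8,
    n_pathways: int = 1,
    K_D_ca: float = CENTRAL_KD_CA,
) -> NetworkSpec:
    """Build a randomized bipartite E-I network.

    ``g_syn_central`` values are the total incoming conductance per
    postsynaptic cell; per-connection centrals are divided by the presynaptic
    population size so the aggregate drive is independent of network size.
    ``clustered`` names receptor types (e.g. ``("GABA_B",)``) whose weights
    get the normalized Gaussian spatial profile with spread ``cluster_c``.
    """
    if n_E < 1 or n_I < 1:
        raise ValueError("populations must contain at least one cell")
    central = dict(CENTRAL_G_SYN)
    if g_syn_central:
        central.update(g_syn_central)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    ss_params, ss_w = ss.spawn(2)
    params = sample_neuron_params(
        np.random.default_rng(ss_params), n_E + n_I, cat_mode=cat_mode, K_D_ca=K_D_ca
    )

    rng_w = np.random.default_rng(ss_w)
    w = {
        "AMPA": _sample_weights(rng_w, central["AMPA"] / n_E, (n_I, n_E)),
        "GABA_A": _sample_weights(rng_w, central["GABA_A"] / n_I, (n_E, n_I)),
        "GABA_B": _sample_weights(rng_w, central["GABA_B"] / n_I, (n_E, n_I)),
    }
    pos = {
        "AMPA": (_positions(n_E, n_I), _positions(n_I, n_I)),
        "GABA_A": (_positions(n_I, n_E), _positions(n_E, n_E)),
        "GABA_B": (_positions(n_I, n_E), _positions(n_E, n_E)),
    }
    for rec in clustered:
        pre, post = pos[rec]
        w[rec] = gaussian_clustered_weights(w[rec], pre, post, c=cluster_c)

    seed_int = seed if isinstance(seed, (int, np.integer)) else None
    return NetworkSpec(
        n_E=n_E,
        n_I=n_I,
        params=params,
        W_ampa=w["AMPA"],
        W_gaba_a=w["GABA_A"],
        W_gaba_b=w["GABA_B"],
        pathways=_pathway_assignment(n_I, n_pathways),
        seed=seed_int,
        g_syn_central=central,
        clustered=tuple(clustered),
        cluster_c=cluster_c,
        n_pathways=n_pathways,
    )


def reference_circuit(cat_mode: CatMode = "slow") -> NetworkSpec:
    """The deterministic reference two-cell circuit: every sampled parameter
    at its range midpoint and every synaptic weight at its central value."""
    spec = build_network(1, 1, seed=0, cat_mode=cat_mode)
    mids = {k: 0.5 * (lo + hi) for k, (lo, hi) in PARAM_RANGES.items()}
    for name, val in mids.items():
        np.asarray(getattr(spec.params, name))[:] = val
    spec.W_ampa[:] = CENTRAL_G_SYN["AMPA"]
    spec.W_gaba_a[:] = CENTRAL_G_SYN["GABA_A"]
    spec.W_gaba_b[:] = CENTRAL_G_SYN["GABA_B"]
    return spec


def perturb_modulation(spec: NetworkSpec, seed: int) -> NetworkSpec:
    """Global neuromodulation / synaptic-plasticity perturbation.

    Resamples every cell's maximal conductances and every synaptic weight
    from their original uniform ranges with a fresh seed; the topology
    (population sizes, all-to-all mask, clustering profile, pathway layout)
    is untouched.
    """
    return build_network(
        spec.n_E,
        spec.n_I,
        seed=seed,
        cat_mode=spec.cat_mode,
        g_syn_central=spec.g_syn_central,
        clustered=spec.clustered,
        cluster_c=spec.cluster_c,
        n_pathways=spec.n_pathways,
        K_D_ca=float(np.asarray(spec.params.K_D_ca).ravel()[0])
        if np.ndim(spec.params.K_D_ca)
        else spec.params.K_D_ca,
    )
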