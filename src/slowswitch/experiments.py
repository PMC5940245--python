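"""Scripted reproductions of the model's experiment battery.

Each function builds its random inputs from a master seed, runs the
simulation engine, and returns tidy pandas tables (plus trace objects where
spectral analysis needs them).  The canonical stimulus is the network-switch
protocol: spontaneous activity, then a hyperpolarizing current step
(default -2.6 uA/cm^2, the reference amplitude) onto the inhibitory
population, then release.

Epoch layout (defaults, ms): 500 settle | 2500 pre | 6000 during | 2000 post.
Classification windows discard the settle period and the first second of the
during epoch (rhythm ignition transient).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .analysis import analyze_circuit, classify_circuit, detect_switch, segment_bursts
from .engine import integrate, integrate_batch
from .lfp import band_power_ratio, compute_lfp, peak_frequency, spectrogram
from .network import NetworkSpec, build_network
from .protocols import StimulusProtocol

__all__ = [
    "SwitchEpochs",
    "switch_stimulus",
    "run_two_cell_switch",
    "run_ensemble_switch",
    "run_rhythm_distributions",
    "run_size_scaling",
    "run_pathway_modulation",
    "run_transfer_mode",
    "run_single_cell_protocols",
    "I_APP_GRID",
]

#: Reference hyperpolarizing current (uA/cm^2) and the five-level grid used
#: for the ensemble bar graphs (only the reference level is canonical; the
#: grid spacing is implementation-chosen and config-exposed).
I_APP_REF = -2.6
I_APP_GRID = (-1.0, -1.8, -2.6, -3.4, -4.2)


@dataclass(frozen=True)
class SwitchEpochs:
    """Timing of the canonical switch protocol (ms)."""

    settle: float = 500.0
    pre: float = 2500.0
    during: float = 6000.0
    post: float = 2000.0
    ignition: float = 1000.0   # excluded from the during-epoch classification

    @property
    def t_on(self) -> float:
        return self.settle + self.pre

    @property
    def t_off(self) -> float:
        return self.t_on + self.during

    @property
    def t_end(self) -> float:
        return self.t_off + self.post

    @property
    def pre_window(self) -> tuple[float, float]:
        return (self.settle, self.t_on)

    @property
    def during_window(self) -> tuple[float, float]:
        return (self.t_on + self.ignition, self.t_off)

    @property
    def post_window(self) -> tuple[float, float]:
        return (self.t_off, self.t_end)


def switch_stimulus(epochs: SwitchEpochs, amplitude: float = I_APP_REF,
                    target="I") -> StimulusProtocol:
    return StimulusProtocol().step(epochs.t_on, epochs.t_off, amplitude, target=target)


def _circuit_seeds(seed: int, n: int) -> list:
    return np.random.SeedSequence(seed).spawn(n)


def run_two_cell_switch(seed: int = 0, epochs: SwitchEpochs | None = None,
                        cat_mode: str = "slow", dt: float = 0.05):
    """Single two-cell E-I circuit under the canonical switch protocol.

    Returns (result, report) where the report collects the pre/during/post
    circuit labels and the during-epoch rhythm metrics.
    """
    epochs = epochs or SwitchEpochs()
    spec = build_network(1, 1, seed=seed, cat_mode=cat_mode)
    res = integrate(spec, switch_stimulus(epochs), t_end=epochs.t_end, dt=dt)
    labels = {
        name: classify_circuit(res.spikes, win, spec.n_E)
        for name, win in (
            ("pre", epochs.pre_window),
            ("during", epochs.during_window),
            ("post", epochs.post_window),
        )
    }
    report = analyze_circuit(res, epochs.during_window)
    return res, {"labels": labels, "rhythm": report,
                 "switched": detect_switch(labels["pre"], labels["during"])}


def run_ensemble_switch(
    n: int = 1000,
    I_app_list=(I_APP_REF,),
    cat_mode: str = "slow",
    seed: int = 0,
    epochs: SwitchEpochs | None = None,
    dt: float = 0.05,
    chunk: int = 500,
) -> pd.DataFrame:
    """Ensemble of random two-cell circuits under hyperpolarizing steps.

    One row per (circuit, I_app): the pre/during labels, the switch flag,
    and the during-epoch rhythm metrics of each cell.  Circuits are sampled
    once per ensemble and re-used across current levels, as in a repeated
    stimulation experiment.
    """
    epochs = epochs or SwitchEpochs()
    seeds = _circuit_seeds(seed, n)
    rows = []
    for i_app in I_app_list:
        proto = switch_stimulus(epochs, amplitude=i_app)
        for lo in range(0, n, chunk):
            idx = range(lo, min(lo + chunk, n))
            specs = [build_network(1, 1, seed=seeds[k], cat_mode=cat_mode) for k in idx]
            results = integrate_batch(
                specs, proto, t_end=epochs.t_off, dt=dt,
                record_v=False, record_syn=False,
            )
            for k, res in zip(idx, results):
                pre = classify_circuit(res.spikes, epochs.pre_window, 1)
                dur = classify_circuit(res.spikes, epochs.during_window, 1)
                rep = analyze_circuit(res, epochs.during_window)
                pre_rates = [
                    1e3 * len(s) / (epochs.pre_window[1] - epochs.pre_window[0])
                    for s in res.spikes_in(epochs.pre_window)
                ]
                rows.append(
                    {
                        "circuit": k,
                        "I_app": i_app,
                        "pre_label": pre,
                        "during_label": dur,
                        "switched": detect_switch(pre, dur),
                        "tonic_to_sync": pre == "tonic_spiking" and dur == "bursting_sync",
                        "sync_during": dur == "bursting_sync",
                        "blown_up": res.blown_up,
                        "PER": rep.PER,
                        "SPB": rep.SPB,
                        "IBF": rep.IBF,
                        "DC": rep.DC,
                        "pre_rate_E": pre_rates[0],
                        "pre_rate_I": pre_rates[1],
                        "IBF_I": _cell_ibf(res, 1, epochs.during_window),
                        "IBF_E": _cell_ibf(res, 0, epochs.during_window),
                    }
                )
    return pd.DataFrame(rows)


def _cell_ibf(res, cell: int, window) -> float:
    train = res.spikes_in(window)[cell]
    bursts = segment_bursts(train)
    if len(bursts) < 2:
        return np.nan
    return float(np.mean([1e3 * (b.n_spikes - 1) / b.duration for b in bursts]))


def run_rhythm_distributions(n: int = 1000, seed: int = 0,
                             table: pd.DataFrame | None = None) -> dict:
    """Rhythm-metric distributions of the switching / bursting sub-ensembles.

    ``switching``: circuits whose tonic-spiking pre state turns into
    synchronized bursting (per-circuit inhibitory tonic rate vs intraburst
    frequency).  ``bursting``: circuits synchronized during hyperpolarization
    regardless of pre state (bursting frequency 1000/PER in Hz, duty cycle).
    Pass a precomputed ensemble ``table`` to avoid re-simulation.
    """
    if table is None:
        table = run_ensemble_switch(n=n, seed=seed)
    ref = table[table.I_app == I_APP_REF]
    switching = ref[ref.tonic_to_sync].copy()
    bursting = ref[ref.sync_during].copy()
    bursting["burst_freq_hz"] = 1e3 / bursting.PER
    return {
        "table": table,
        "switching": switching,
        "bursting": bursting,
        "n_switching": int(len(switching)),
        "n_bursting": int(len(bursting)),
    }


def run_size_scaling(
    sizes=(10, 40, 100),
    n_networks: int = 100,
    seed: int = 0,
    epochs: SwitchEpochs | None = None,
    dt: float = 0.05,
) -> pd.DataFrame:
    """Peak LFP frequency during hyperpolarization vs network size.

    Networks of ``size`` cells are split evenly into E and I populations.
    Returns one row per network with the peak frequency of the excitatory
    LFP in the during window.
    """
    epochs = epochs or SwitchEpochs()
    rows = []
    for size in sizes:
        n_e = n_i = size // 2
        seeds = np.random.SeedSequence((seed, size)).spawn(n_networks)
        specs = [build_network(n_e, n_i, seed=s) for s in seeds]
        results = integrate_batch(
            specs, switch_stimulus(epochs), t_end=epochs.t_off, dt=dt,
            record_v=False, record_syn=True,
        )
        for k, res in enumerate(results):
            lfp = compute_lfp(res, "E")
            rows.append(
                {
                    "size": size,
                    "network": k,
                    "peak_freq_hz": peak_frequency(lfp, epochs.during_window),
                    "blown_up": res.blown_up,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class PathwayScheduleEntry:
    pathway: int
    t_on: float
    t_off: float


def run_pathway_modulation(
    n_E: int = 80,
    n_I: int = 80,
    n_pathways: int = 8,
    schedule: list[PathwayScheduleEntry] | None = None,
    clustered: tuple = (),
    g_syn_central: dict | None = None,
    amplitude: float = I_APP_REF,
    seed: int = 0,
    t_end: float | None = None,
    dt: float = 0.05,
) -> dict:
    """Pathway-resolved hyperpolarization of inhibitory sub-populations.

    Default layout is the 160-cell network with 8 modulatory pathways and a
    staggered schedule (pathway k active on [1500 + k*2000, t_end - 500)).
    With ``clustered=("GABA_B",)`` and 4 pathways this becomes the spatially
    clustered 40-cell layout where each pathway controls its own E-cluster
    rhythm; spatial control requires the clustered receptor to carry the
    dominant share of inhibition, so that layout defaults to the
    GABA_B-dominant (low-ratio) synaptic configuration.  Returns the
    simulation result, per-cluster E-population LFPs and spectrograms.
    """
    if g_syn_central is None and clustered:
        g_syn_central = {"GABA_A": 0.5, "GABA_B": 1.6}
    spec = build_network(
        n_E, n_I, seed=seed, clustered=clustered, n_pathways=n_pathways,
        g_syn_central=g_syn_central,
    )
    if schedule is None:
        t_end = t_end or 1500.0 + n_pathways * 2000.0 + 2500.0
        schedule = [
            PathwayScheduleEntry(k, 1500.0 + k * 2000.0, t_end - 500.0)
            for k in range(n_pathways)
        ]
    t_end = t_end or max(e.t_off for e in schedule) + 500.0
    proto = StimulusProtocol()
    for e in schedule:
        proto.step(e.t_on, e.t_off, amplitude, target=("pathway", e.pathway))
    res = integrate(spec, proto, t_end=t_end, dt=dt, record_v=False, record_syn=True)

    # E-cluster c = the excitatory cells spatially aligned with I-pathway c
    cluster_of_e = (np.arange(n_E) * n_pathways) // n_E
    out = {"result": res, "spec": spec, "schedule": schedule, "clusters": {}}
    for c in range(n_pathways):
        cells = np.nonzero(cluster_of_e == c)[0]
        lfp = compute_lfp(res, "E", cells=cells)
        t_s, f_s, sxx = spectrogram(lfp)
        out["clusters"][c] = {"lfp": lfp, "spectrogram": (t_s, f_s, sxx)}
    return out


def run_transfer_mode(
    ratio_configs: dict | None = None,
    seed: int = 0,
    n_E: int = 20,
    n_I: int = 20,
    pulse_amp: float = 8.0,
    pulse_ms: float = 10.0,
    sine_amp: float = 2.5,
    sine_offset: float = 5.0,
    sine_freq_hz: float = 0.5,
    dt: float = 0.05,
) -> pd.DataFrame:
    """Transfer properties of the active state under GABA_A:GABA_B ratio changes.

    For each ratio configuration the 40-cell network receives, in the active
    state, a short excitatory pulse and a slow biased sinusoidal drive to the
    E cells; afterwards the canonical hyperpolarization verifies the network
    switch still operates (mean-field criterion: slow-band LFP power during
    hyperpolarization at least tenfold the active-state level).  Returns one
    row per (ratio, time-bin) with the mean E-population rate; per-ratio
    scalars (switch flag, pulse spike/burst counts, peak sine phase) ride
    along on every row of that ratio.

    With GABA_A dominant the E cells answer the pulse with a single spike
    and track the sinusoid with a rate peaking at its crest (linear-like);
    with GABA_B dominant they sit near the K reversal, answer the pulse with
    a T-type burst and concentrate their response at the rising-phase onset
    (detector-like).
    """
    if ratio_configs is None:
        ratio_configs = {
            "high": {"GABA_A": 2.5, "GABA_B": 0.8},
            "low": {"GABA_A": 0.5, "GABA_B": 1.6},
        }
    t_pulse = 2000.0
    t_sine_on, t_sine_off = 4000.0, 12000.0
    t_hyp_on, t_hyp_off = 13000.0, 19000.0
    t_end = 19500.0
    bin_ms = 100.0
    rows = []
    for name, g_syn in ratio_configs.items():
        spec = build_network(n_E, n_I, seed=seed, g_syn_central=g_syn)
        proto = StimulusProtocol()
        proto.step(t_pulse, t_pulse + pulse_ms, pulse_amp, target="E")
        proto.sine(t_sine_on, t_sine_off, sine_amp, sine_freq_hz,
                   offset=sine_offset, target="E")
        proto.step(t_hyp_on, t_hyp_off, I_APP_REF, target="I")
        res = integrate(spec, proto, t_end=t_end, dt=dt, record_v=False,
                        record_syn=True)
        lfp = compute_lfp(res, "E")
        switched = bool(
            band_power_ratio(lfp, (t_hyp_on + 1000.0, t_hyp_off), (500.0, t_pulse))
            >= 10.0
        )
        e_trains = res.spikes[:n_E]
        e_spikes = np.sort(np.concatenate(e_trains))
        pulse_win = (t_pulse, t_pulse + 300.0)
        pulse_spikes = int(np.sum((e_spikes >= pulse_win[0]) & (e_spikes < pulse_win[1])))
        pulse_bursts = sum(
            len(
                segment_bursts(
                    np.asarray(t)[(np.asarray(t) >= pulse_win[0]) & (np.asarray(t) < pulse_win[1])],
                    theta_intra=40.0,
                )
            )
            for t in e_trains
        )
        sine = e_spikes[(e_spikes >= t_sine_on) & (e_spikes < t_sine_off)]
        phases = ((sine - t_sine_on) * 1e-3 * sine_freq_hz) % 1.0
        hist, _ = np.histogram(phases, np.linspace(0.0, 1.0, 11))
        peak_phase = (np.argmax(hist) + 0.5) / 10.0 if hist.any() else np.nan

        edges = np.arange(0.0, t_end + bin_ms, bin_ms)
        counts, _ = np.histogram(e_spikes, edges)
        rate = counts / (n_E * bin_ms * 1e-3)  # spikes/s per cell
        centers = edges[:-1] + bin_ms / 2
        phase = np.where(
            (centers >= t_sine_on) & (centers < t_sine_off),
            ((centers - t_sine_on) * 1e-3 * sine_freq_hz) % 1.0,
            np.nan,
        )
        for c, r_, ph in zip(centers, rate, phase):
            rows.append(
                {
                    "ratio": name,
                    "t_ms": c,
                    "rate_hz": r_,
                    "sine_phase": ph,
                    "switched": switched,
                    "pulse_spikes": pulse_spikes,
                    "pulse_bursts": pulse_bursts,
                    "peak_sine_phase": peak_phase,
                }
            )
    return pd.DataFrame(rows)


def run_single_cell_protocols(
    params_list=None,
    seed: int = 0,
    n: int = 20,
    cat_mode: str = "slow",
    amplitude: float = I_APP_REF,
    dt: float = 0.05,
    rb_isi_ms: float = 15.0,
) -> pd.DataFrame:
    """Hyperpolarize-and-release protocol on isolated neurons.

    Labels: ``HIB`` (sustained bursting while hyperpolarized), ``RB``
    (transient bursting after release), ``PIR`` (transient spiking after
    release without a burst), ``none``.  ``params_list`` may carry explicit
    seeds; otherwise ``n`` random cells are drawn from the master seed.

    A rebound *burst* is a high-frequency spike cluster (intra-burst ISI
    below ``rb_isi_ms``, i.e. intraburst frequency well above the tonic
    rate); the instantaneous-activation model produces a decelerating
    fast-tonic rebound instead, whose ISIs never reach burst compactness —
    that is what separates RB from PIR here.
    """
    t_on, t_off, t_end = 2000.0, 5000.0, 7000.0
    if params_list is None:
        params_list = list(np.random.SeedSequence(seed).spawn(n))
    specs = []
    for s in params_list:
        spec = build_network(1, 1, seed=s, cat_mode=cat_mode)
        spec.W_ampa[:] = 0.0
        spec.W_gaba_a[:] = 0.0
        spec.W_gaba_b[:] = 0.0
        specs.append(spec)
    proto = StimulusProtocol().step(t_on, t_off, amplitude, target="all")
    results = integrate_batch(specs, proto, t_end=t_end, dt=dt,
                              record_v=False, record_syn=False)
    rows = []
    for k, res in enumerate(results):
        train = np.asarray(res.spikes[0])
        during = train[(train >= t_on + 500.0) & (train < t_off)]
        release = train[(train >= t_off) & (train < t_off + 1000.0)]
        hib = len(segment_bursts(during)) >= 2
        rb = len(segment_bursts(release, theta_intra=rb_isi_ms)) >= 1
        pir = (not rb) and int(np.sum(release < t_off + 300.0)) >= 2
        label = "HIB" if hib else "RB" if rb else "PIR" if pir else "none"
        rows.append({"cell": k, "label": label,
                     "n_during": during.size, "n_release": release.size})
    return pd.DataFrame(rows)
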