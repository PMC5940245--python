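"""Mean-field observables: LFP synthesis, filtering, spectrograms.

The local field potential of a population is modeled as the sum of the
postsynaptic currents into its cells divided by the cell count (1/N
normalization, which is what makes the mean field converge as populations
grow), sampled at F_s = 1 kHz and low-pass filtered at 100 Hz with a
fourth-order Butterworth filter.  Filtering is applied forward-backward
(zero phase) so LFP features stay aligned with spike times.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = ["LFPTrace", "compute_lfp", "spectrogram", "peak_frequency"]

FS = 1000.0           # Hz
LOWPASS_HZ = 100.0
FILTER_ORDER = 4


@dataclass
class LFPTrace:
    """LFP samples at 1 kHz with their time axis (ms)."""

    t: np.ndarray
    x: np.ndarray
    fs: float = FS
    population: str = "E"
    meta: dict = field(default_factory=dict)

    def window(self, window: tuple[float, float]) -> np.ndarray:
        lo, hi = window
        return self.x[(self.t >= lo) & (self.t < hi)]


def compute_lfp(result, population: str = "E", cells: np.ndarray | None = None,
                lowpass: bool = True) -> LFPTrace:
    """LFP of one population (or a sub-cluster of it) from a simulation result.

    Excitatory cells receive GABA_A + GABA_B currents, inhibitory cells
    receive AMPA; the LFP is their per-cell-count-normalized sum.  ``cells``
    optionally restricts to a subset of within-population indices (e.g. one
    spatial cluster of the excitatory population).
    """
    if not result.syn_currents:
        raise ValueError("simulation was run without synaptic-current recording")
    if population == "E":
        cur = result.syn_currents["GABA_A"] + result.syn_currents["GABA_B"]
    elif population == "I":
        cur = result.syn_currents["AMPA"]
    else:
        raise ValueError(f"unknown population {population!r}")
    if cells is not None:
        cur = cur[np.asarray(cells, dtype=int)]
    x = cur.sum(axis=0) / cur.shape[0]
    if lowpass and x.size > 3 * (FILTER_ORDER + 1):
        sos = signal.butter(FILTER_ORDER, LOWPASS_HZ, btype="low", fs=FS, output="sos")
        x = signal.sosfiltfilt(sos, x)
    return LFPTrace(t=np.asarray(result.t, dtype=float), x=x, population=population,
                    meta={"lowpass_hz": LOWPASS_HZ if lowpass else None})


def spectrogram(lfp: LFPTrace, window_ms: float = 1024.0, overlap: float = 0.9):
    """Log-power short-time Fourier spectrogram of the LFP.

    Hann-tapered windows of ``window_ms`` with fractional ``overlap``;
    returns (t_ms, f_hz, log10 power) with frequencies up to Nyquist
    (500 Hz at the 1 kHz sampling rate).
    """
    nper = int(round(window_ms * lfp.fs / 1000.0))
    if lfp.x.size < nper:
        raise ValueError("LFP shorter than the spectrogram window")
    f, tt, sxx = signal.spectrogram(
        lfp.x,
        fs=lfp.fs,
        window="hann",
        nperseg=nper,
        noverlap=int(round(overlap * nper)),
        detrend="constant",
        scaling="density",
        mode="psd",
    )
    return tt * 1000.0 + lfp.t[0], f, np.log10(sxx + 1e-300)


def band_power_ratio(
    lfp: LFPTrace,
    window: tuple[float, float],
    reference: tuple[float, float],
    band: tuple[float, float] = (1.0, 20.0),
) -> float:
    """Slow-band LFP power in ``window`` relative to a ``reference`` window.

    The oscillatory network state announces itself as a marked high-power
    band in the low frequencies; a ratio well above 1 against the active
    state marks the switch at the mean-field level.
    """
    def _power(win):
        x = lfp.window(win)
        x = x - np.mean(x)
        f, pxx = signal.periodogram(x, fs=lfp.fs)
        sel = (f >= band[0]) & (f <= band[1])
        return float(np.trapezoid(pxx[sel], f[sel]))

    p_ref = _power(reference)
    return _power(window) / max(p_ref, 1e-300)


def is_oscillatory(
    lfp: LFPTrace,
    window: tuple[float, float],
    reference: tuple[float, float],
    band: tuple[float, float] = (1.0, 20.0),
    factor: float = 10.0,
) -> bool:
    """Mean-field state test: does ``window`` carry a slow rhythmic band
    at least ``factor`` times stronger than the reference (active) epoch?"""
    return band_power_ratio(lfp, window, reference, band) >= factor


def peak_frequency(lfp: LFPTrace, window: tuple[float, float] | None = None) -> float:
    """Frequency (Hz) of maximal average power, DC bin excluded.

    Computed from the periodogram of the (optionally windowed) trace; a flat
    signal has no peak and returns NaN.
    """
    x = lfp.window(window) if window is not None else lfp.x
    x = x - np.mean(x)
    if x.size < 8 or np.allclose(x, 0.0, atol=1e-12 * max(1.0, np.max(np.abs(x)))):
        return float("nan")
    f, pxx = signal.periodogram(x, fs=lfp.fs, detrend="constant")
    pxx = pxx[1:]       # drop DC
    f = f[1:]
    return float(f[np.argmax(pxx)])
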