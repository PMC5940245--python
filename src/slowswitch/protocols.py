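"""Applied-current stimulus protocols.

A protocol is a list of additive segments, each active on a time interval and
targeted at a cell group: the whole network, one population ("E"/"I"), one
modulatory pathway of inhibitory cells, or an explicit index list.  Segments
are piecewise-constant steps or sinusoids; the canonical network-switch
protocol is a hyperpolarizing step onto the inhibitory population.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Segment", "StimulusProtocol", "switch_protocol"]


@dataclass(frozen=True)
class Segment:
    """One additive stimulus epoch.

    ``target`` is "all", "E", "I", ("pathway", k), or an integer index array.
    For ``kind="sine"`` the current is ``offset + amplitude*sin(2*pi*f*t)``
    with f in Hz (time in ms).
    """

    t_start: float
    t_end: float
    amplitude: float
    target: object = "all"
    kind: str = "step"          # "step" | "sine"
    freq_hz: float = 1.0
    offset: float = 0.0

    def __post_init__(self):
        if self.t_start < 0 or self.t_end <= self.t_start:
            raise ValueError("segment needs 0 <= t_start < t_end")
        if self.kind not in ("step", "sine"):
            raise ValueError(f"unknown segment kind {self.kind!r}")


def _target_mask(target, spec) -> np.ndarray:
    n = spec.n_cells
    mask = np.zeros(n)
    if isinstance(target, str):
        sl = {"all": slice(None), "E": spec.e_slice, "I": spec.i_slice}[target]
        mask[sl] = 1.0
    elif isinstance(target, tuple) and target[0] == "pathway":
        mask[spec.pathway_cells(target[1])] = 1.0
    else:
        mask[np.asarray(target, dtype=int)] = 1.0
    return mask


@dataclass
class StimulusProtocol:
    """Additive piecewise applied-current schedule for one network layout."""

    segments: list = field(default_factory=list)

    def add(self, seg: Segment) -> "StimulusProtocol":
        self.segments.append(seg)
        return self

    def step(self, t_start, t_end, amplitude, target="all") -> "StimulusProtocol":
        return self.add(Segment(t_start, t_end, amplitude, target))

    def sine(self, t_start, t_end, amplitude, freq_hz, offset=0.0, target="all"):
        return self.add(
            Segment(t_start, t_end, amplitude, target, kind="sine", freq_hz=freq_hz, offset=offset)
        )

    @property
    def t_end(self) -> float:
        return max((s.t_end for s in self.segments), default=0.0)

    def compile(self, spec) -> "CompiledProtocol":
        return CompiledProtocol(self, spec)


class CompiledProtocol:
    """Protocol bound to a network layout: fast per-step evaluation."""

    def __init__(self, protocol: StimulusProtocol, spec):
        self.segments = [(s, _target_mask(s.target, spec)) for s in protocol.segments]

    def current(self, t: float) -> np.ndarray | float:
        out = 0.0
        for seg, mask in self.segments:
            if seg.t_start <= t < seg.t_end:
                if seg.kind == "step":
                    amp = seg.amplitude
                else:
                    amp = seg.offset + seg.amplitude * np.sin(
                        2e-3 * np.pi * seg.freq_hz * (t - seg.t_start)
                    )
                out = out + amp * mask
        return out


def switch_protocol(
    settle: float = 500.0,
    pre: float = 2500.0,
    during: float = 5000.0,
    post: float = 2000.0,
    amplitude: float = -2.6,
    target="I",
) -> tuple[StimulusProtocol, dict]:
    """Canonical network-switch protocol: settle, spontaneous activity,
    hyperpolarizing step onto the inhibitory cells, release.

    Returns the protocol and the epoch windows (ms) used by the analysis:
    ``{"pre": (t0, t1), "during": (t0, t1), "post": (t0, t1)}``.
    """
    t0 = settle + pre
    t1 = t0 + during
    proto = StimulusProtocol().step(t0, t1, amplitude, target=target)
    epochs = {
        "pre": (settle, t0),
        "during": (t0, t1),
        "post": (t1, t1 + post),
    }
    return proto, epochs
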