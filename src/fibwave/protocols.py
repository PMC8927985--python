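"""Stimulation protocols: ramp-pacing AF induction (8 beats at each cycle
length from 200 down to 120 ms, 11.52 s total), the 34-s observation run,
and the post-ablation reinduction/observation sequence."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .monodomain import (SimulationTrace, SolverConfig, StimulusEvent,
                         simulate)
from .tissue import TissueModel


class ProtocolError(ValueError):
    pass


@dataclass
class PacingSite:
    """Stimulated node set standing in for the 'anterior LA' pacing site.

    Either a disc at a fractional sheet position (default) or, with
    edge set to left/right/bottom/top, a full edge strip: a strip launches
    a planar wave, which captures reliably on sheets whose transverse
    coupling is near the propagation limit."""
    frac_x: float = 0.5
    frac_y: float = 0.06
    radius_mm: float = 1.5
    edge: str | None = None
    strip_depth_mm: float = 1.0

    def resolve(self, tissue: TissueModel) -> np.ndarray:
        coords = tissue.node_coords
        lx = coords[:, 0].max()
        ly = coords[:, 1].max()
        if self.edge is not None:
            depth = max(self.strip_depth_mm, 1.01 * tissue.spacing_mm)
            axis, near = {"left": (0, True), "right": (0, False),
                          "bottom": (1, True), "top": (1, False)}[self.edge]
            lim = (lx, ly)[axis]
            sel = (coords[:, axis] < depth) if near else (coords[:, axis] > lim - depth)
            nodes = np.flatnonzero(sel & tissue.active)
        else:
            c = np.array([self.frac_x * lx, self.frac_y * ly])
            r = max(self.radius_mm, 1.01 * tissue.spacing_mm)
            d2 = np.sum((coords - c) ** 2, axis=1)
            nodes = np.flatnonzero((d2 < r ** 2) & tissue.active)
        if nodes.size == 0:
            raise ProtocolError("pacing site contains no active node")
        return nodes


@dataclass
class RampProtocol:
    cl_start: float = 200.0
    cl_end: float = 120.0
    cl_step: float = 10.0
    beats_per_cl: int = 8
    pacing_site: PacingSite = field(default_factory=PacingSite)
    stim_amplitude: float = 40.0     # pA/pF
    stim_duration: float = 2.0       # ms

    def __post_init__(self):
        if self.cl_start < self.cl_end:
            raise ProtocolError("cl_start must be >= cl_end")
        if self.beats_per_cl < 1:
            raise ProtocolError("beats_per_cl must be >= 1")
        n = (self.cl_start - self.cl_end) / self.cl_step
        if self.cl_step <= 0 or abs(n - round(n)) > 1e-9:
            raise ProtocolError("cl_step must divide cl_start - cl_end")

    @property
    def cycle_lengths(self):
        n = int(round((self.cl_start - self.cl_end) / self.cl_step)) + 1
        return self.cl_start - self.cl_step * np.arange(n)

    @property
    def span_ms(self):
        """Total schedule span: beats_per_cl x sum of cycle lengths."""
        return float(self.beats_per_cl * np.sum(self.cycle_lengths))


@dataclass
class InductionResult:
    induced: bool
    onset_time: float | None     # ms; present iff induced
    trace: SimulationTrace
    last_activity_ms: float = 0.0


def build_ramp_schedule(protocol: RampProtocol, tissue: TissueModel):
    """Stimulus events of the ramp: each beat occupies its own cycle length,
    so the first stimulus is at t=0 and the schedule spans span_ms."""
    nodes = protocol.pacing_site.resolve(tissue)
    events = []
    t = 0.0
    for cl in protocol.cycle_lengths:
        for _ in range(protocol.beats_per_cl):
            events.append(StimulusEvent(t, nodes, protocol.stim_amplitude,
                                        protocol.stim_duration))
            t += cl
    return events


def induce_af(tissue: TissueModel, profile, protocol: RampProtocol,
              observe_until: float = 34000.0,
              solver: SolverConfig | None = None,
              sustained_ms: float = 1000.0) -> InductionResult:
    """Ramp-pace, then observe to `observe_until` ms.

    induced = self-sustained activity continues at least `sustained_ms`
    beyond the final stimulus.  onset_time is the end of the pacing ramp
    (AF, when present, is established by then)."""
    if observe_until <= protocol.span_ms:
        raise ProtocolError("observation window must outlast the ramp")
    stimuli = build_ramp_schedule(protocol, tissue)
    trace = simulate(tissue, profile, stimuli, observe_until, solver)
    last_stim = stimuli[-1].time
    acts = trace.activation_times()
    last_activity = max((a[-1] for a in acts if a.size), default=0.0)
    induced = last_activity >= last_stim + sustained_ms
    return InductionResult(induced, last_stim if induced else None,
                           trace, last_activity)


def post_ablation_test(tissue_after_ablation: TissueModel, profile,
                       protocol: RampProtocol, observe_ms: float = 10000.0,
                       solver: SolverConfig | None = None):
    """Re-run the ramp on ablated tissue, then classify the rhythm in the
    following `observe_ms` window (AF / AT / TERMINATED)."""
    from .ablation import classify_rhythm
    stimuli = build_ramp_schedule(protocol, tissue_after_ablation)
    span = stimuli[-1].time + protocol.cycle_lengths[-1]
    trace = simulate(tissue_after_ablation, profile, stimuli,
                     span + observe_ms, solver)
    lockout = trace.activation_lockout
    return classify_rhythm(trace, (stimuli[-1].time + lockout, span + observe_ms))
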