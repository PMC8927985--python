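"""Virtual ablation: circumferential PV isolation (CPVI) rings, the
highest-DF target set, rhythm classification of the post-ablation window
(AF / AT / TERMINATED), and the paired two-arm ablation experiment."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .dfmap import DFMap, SEARCH_BAND, df_windows, top_df_area
from .monodomain import SimulationTrace, SolverConfig, apply_conduction_block
from .protocols import RampProtocol, induce_af, post_ablation_test
from .tissue import TissueModel


class AblationError(ValueError):
    pass


@dataclass
class RhythmOutcome:
    label: str                        # AF | AT | TERMINATED
    last_activation_time: float       # ms; 0 when no activation in window
    mean_cycle_length: float | None   # ms
    cycle_length_cv: float | None     # dimensionless
    n_spectral_peaks: int | None

    @property
    def defragmented(self):
        return self.label in ("TERMINATED", "AT")


def cpvi_set(tissue: TissueModel, margin_mm: float = 1.0,
             width_mm: float | None = None) -> np.ndarray:
    """Closed ablation ring encircling each PV opening at `margin_mm`.

    Ring closure is verified by connectivity: after removing the rings the
    rim nodes of each opening must be disconnected from the sheet exterior.
    """
    if not tissue.pv_openings:
        raise AblationError("tissue has no PV opening")
    h = tissue.spacing_mm
    width = width_mm if width_mm is not None else 1.8 * h
    coords = tissue.node_coords
    ring = np.zeros(tissue.n_nodes, dtype=bool)
    inner_all = np.zeros(tissue.n_nodes, dtype=bool)
    lx, ly = coords[:, 0].max(), coords[:, 1].max()
    for cx, cy, r in tissue.pv_openings:
        r_in = r + margin_mm
        if cx - r_in - width < 0 or cx + r_in + width > lx \
                or cy - r_in - width < 0 or cy + r_in + width > ly:
            raise AblationError("CPVI ring would exit the tissue bounds")
        d = np.hypot(coords[:, 0] - cx, coords[:, 1] - cy)
        ring |= (d >= r_in) & (d < r_in + width)
        inner_all |= d < r_in
    ring &= tissue.active

    # connectivity check: exterior vs. inside-the-ring components
    ny, nx = tissue.ny, tissue.nx
    open_grid = (tissue.active & ~ring).reshape(ny, nx)
    labels, _ = ndimage.label(open_grid, structure=np.array(
        [[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    flat = labels.reshape(-1)
    exterior = flat[np.flatnonzero(tissue.active & ~ring & ~inner_all)]
    ext_label = np.bincount(exterior[exterior > 0]).argmax()
    inner_open = tissue.active & ~ring & inner_all
    if np.any(flat[inner_open] == ext_label):
        raise AblationError("CPVI ring is not closed (interior reachable)")
    return np.flatnonzero(ring)


def df_ablation_set(dfmap: DFMap, window_index: int, tissue: TissueModel,
                    mode="value", fraction=0.05) -> np.ndarray:
    """Highest-DF target nodes, excluding already-ablated nodes."""
    nodes = top_df_area(dfmap, window_index, mode, fraction)
    nodes = nodes[~tissue.ablated[nodes]]
    if nodes.size == 0:
        raise AblationError("DF target empty after excluding ablated nodes")
    defined = np.isfinite(dfmap.df[:, window_index])
    if nodes.size >= 0.9 * defined.sum():
        warnings.warn("DF map nearly uniform: target covers most of the sheet")
    return nodes


def _organized_power_fraction(sig, dt_ms, band=SEARCH_BAND, half_width_hz=0.5):
    """Fraction of band power carried by the dominant peak and its harmonics."""
    x = (sig - sig.mean()) * np.hanning(sig.size)
    p = np.abs(np.fft.rfft(x)) ** 2
    f = np.fft.rfftfreq(sig.size, d=dt_ms / 1000.0)
    sel = (f >= band[0]) & (f <= band[1])
    if not sel.any() or p[sel].sum() <= 0:
        return 0.0, 0
    f0 = f[sel][np.argmax(p[sel])]
    organized = np.zeros_like(sel)
    k = 1
    while k * f0 <= band[1]:
        organized |= np.abs(f - k * f0) <= half_width_hz
        k += 1
    frac = p[sel & organized].sum() / p[sel].sum()
    from scipy.signal import find_peaks
    peaks, _ = find_peaks(p[sel], height=0.2 * p[sel].max())
    return float(frac), int(len(peaks))


def classify_rhythm(trace: SimulationTrace, window,
                    at_cv_threshold: float = 0.1,
                    at_power_threshold: float = 0.6) -> RhythmOutcome:
    """Classify the rhythm in (start_ms, end_ms).

    TERMINATED: no activation in the window.  AT: organized activity —
    coefficient of variation of per-node cycle lengths < at_cv_threshold
    and the dominant global spectral peak (with harmonics) carries more
    than at_power_threshold of 0.5-20 Hz power.  Otherwise AF."""
    t0, t1 = window
    if t1 * 1.0 > trace.t[-1] + trace.dt_record / 2 or t0 < 0:
        raise ValueError("classification window outside the trace")
    acts = trace.activation_times()
    in_win = [a[(a >= t0) & (a <= t1)] for a in acts]
    all_acts = [a for a in in_win if a.size]
    if not all_acts:
        return RhythmOutcome("TERMINATED", 0.0, None, None, None)
    last = max(a[-1] for a in all_acts)
    cls = np.concatenate([np.diff(a) for a in in_win if a.size >= 2])
    if cls.size == 0:
        # isolated final activations, no sustained rhythm
        return RhythmOutcome("TERMINATED", last, None, None, None)
    mean_cl = float(np.mean(cls))
    cv = float(np.std(cls) / mean_cl)
    i0 = int(round(t0 / trace.dt_record))
    i1 = int(round(t1 / trace.dt_record))
    # per-node spectra (median over a node sample): a circulating rhythm has
    # staggered phases, so a global mean signal would cancel itself out
    active_nodes = [k for k, a in enumerate(in_win) if a.size >= 2]
    step = max(1, len(active_nodes) // 64)
    fracs, peaks = [], []
    for k in active_nodes[::step]:
        f, npk = _organized_power_fraction(trace.V[i0:i1, k].astype(float),
                                           trace.dt_record)
        fracs.append(f)
        peaks.append(npk)
    frac = float(np.median(fracs)) if fracs else 0.0
    n_peaks = int(np.median(peaks)) if peaks else 0
    label = "AT" if (cv < at_cv_threshold and frac > at_power_threshold) else "AF"
    return RhythmOutcome(label, last, mean_cl, cv, n_peaks)


@dataclass
class ExperimentReport:
    arm: str
    baseline_induced: bool
    outcome: RhythmOutcome | None
    defragmentation: bool | None
    n_ablated: int
    skipped: bool = False
    baseline_label: str | None = None


def run_ablation_experiment(tissue: TissueModel, profile,
                            protocol: RampProtocol, arm: str,
                            solver: SolverConfig | None = None,
                            baseline=None, dfmap: DFMap | None = None,
                            df_window_index: int = 2) -> ExperimentReport:
    """One ablation arm: CPVI alone or CPVI plus highest-5%-DF ablation.

    The DF target is taken from the baseline AF run's map (last window by
    default).  Pass `baseline` / `dfmap` to share one baseline run across
    paired arms.  If baseline AF is not inducible the experiment is skipped.
    """
    if arm not in ("cpvi_only", "cpvi_plus_df"):
        raise AblationError(f"unknown arm {arm!r}")
    if baseline is None:
        baseline = induce_af(tissue, profile, protocol, solver=solver)
    if not baseline.induced:
        return ExperimentReport(arm, False, None, None, 0, skipped=True)
    ring = cpvi_set(tissue)
    ablated = apply_conduction_block(tissue, ring)
    target = np.empty(0, dtype=int)
    if arm == "cpvi_plus_df":
        if dfmap is None:
            dfmap = df_windows(baseline.trace, tissue)
        target = df_ablation_set(dfmap, df_window_index, ablated)
        # the reinduction pacing site is never lesioned (pacing is delivered
        # from a non-ablated site, as in the clinical protocol)
        site = protocol.pacing_site.resolve(tissue)
        target = np.setdiff1d(target, site)
        ablated = apply_conduction_block(ablated, target)
    outcome = post_ablation_test(ablated, profile, protocol, solver=solver)
    base_label = classify_rhythm(
        baseline.trace,
        (protocol.span_ms + baseline.trace.activation_lockout,
         baseline.trace.t[-1])).label
    return ExperimentReport(arm, True, outcome, outcome.defragmented,
                            int(ring.size + target.size),
                            baseline_label=base_label)
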