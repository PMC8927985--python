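"""APD restitution: per-node (DI, APD90) extraction during ramp pacing,
exponential restitution-curve fitting, and Smax maps.

The fitted form is y(DI) = y0 - A1 * (1 - exp(-DI / tau1)) with free y0 and
A1 and time constant tau1 [ms].  The maximal restitution slope is evaluated
at the minimum observed DI, Smax = (|A1| / tau1) * exp(-DI_min / tau1);
|A1| makes ascending restitution (A1 < 0 in this parameterization) yield a
positive slope.  The DI -> 0 limit |A1|/tau1 is kept as a diagnostic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .monodomain import SimulationTrace
from .tissue import TissueModel

MIN_PAIRS = 4
MIN_DI_SPREAD = 10.0   # ms


@dataclass
class Beat:
    upstroke: float          # ms
    peak_v: float            # mV
    dia_v: float             # mV, diastolic minimum preceding the upstroke
    apd90: float | None      # ms; None if the beat never repolarized to 90%
    repol_time: float | None  # ms, absolute time of 90% repolarization


@dataclass
class RestitutionData:
    node_id: int
    pairs: np.ndarray        # (k, 2) columns (DI, APD90) in beat order

    @property
    def fit_ready(self):
        return (len(self.pairs) >= MIN_PAIRS
                and np.ptp(self.pairs[:, 0]) > MIN_DI_SPREAD)


@dataclass
class RestitutionFit:
    node_id: int
    y0: float
    a1: float
    tau1: float
    smax: float
    smax_di0: float          # diagnostic: slope limit at DI -> 0
    rms_residual: float
    n_pairs: int


def beat_features(t, v, threshold=-40.0, lockout=50.0):
    """Segment a single-node potential series into beats.

    APD90 is measured per beat from its upstroke to 90% repolarization,
    where the 90% level is relative to that beat's own peak and the
    diastolic minimum immediately preceding its upstroke."""
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    ups_idx = []
    cross = np.flatnonzero((v[:-1] < threshold) & (v[1:] >= threshold))
    last = -np.inf
    for i in cross:
        ti = t[i] + (t[i + 1] - t[i]) * (threshold - v[i]) / (v[i + 1] - v[i])
        if ti - last >= lockout:
            ups_idx.append((i, ti))
            last = ti
    beats = []
    for b, (i, ti) in enumerate(ups_idx):
        j_end = ups_idx[b + 1][0] if b + 1 < len(ups_idx) else len(v) - 1
        i_prev = ups_idx[b - 1][0] if b > 0 else 0
        dia = v[i_prev:i + 1].min()
        seg = v[i:j_end + 1]
        tseg = t[i:j_end + 1]
        pk_i = int(np.argmax(seg))
        pk = seg[pk_i]
        level = dia + 0.1 * (pk - dia)
        apd = repol = None
        below = np.flatnonzero(seg[pk_i:] <= level)
        if below.size:
            q = pk_i + below[0]
            if q > 0:
                frac = (seg[q - 1] - level) / (seg[q - 1] - seg[q])
                repol = tseg[q - 1] + frac * (tseg[q] - tseg[q - 1])
            else:
                repol = tseg[q]
            apd = repol - ti
        beats.append(Beat(ti, pk, dia, apd, repol))
    return beats


def extract_apd_di(trace: SimulationTrace, node_id: int,
                   until_ms: float | None = None) -> RestitutionData:
    """(DI, APD90) pairs for one node from consecutive beats.

    DI is the interval from the preceding beat's 90% repolarization to the
    upstroke; the first beat (no preceding DI) is excluded.  Beats with
    upstroke after `until_ms` are discarded."""
    v = trace.V[:, node_id].astype(float)
    beats = beat_features(trace.t, v, trace.activation_threshold,
                          trace.activation_lockout)
    if until_ms is not None:
        beats = [b for b in beats if b.upstroke <= until_ms]
    pairs = []
    for prev, cur in zip(beats[:-1], beats[1:]):
        if prev.repol_time is None or cur.apd90 is None:
            continue
        di = cur.upstroke - prev.repol_time
        if di > 0 and cur.apd90 > 0:
            pairs.append((di, cur.apd90))
    return RestitutionData(node_id, np.asarray(pairs).reshape(-1, 2))


def _model(di, y0, a1, tau1):
    return y0 - a1 * (1.0 - np.exp(-di / tau1))


def fit_restitution(data: RestitutionData) -> RestitutionFit | None:
    """Multi-start nonlinear least squares of the exponential restitution
    curve.  Returns None (node unfit) when there are too few pairs, too
    little DI spread, or no start converges."""
    if not data.fit_ready:
        return None
    di = data.pairs[:, 0]
    apd = data.pairs[:, 1]
    rng_apd = max(np.ptp(apd), 1.0)
    best = None
    for a1_0 in (rng_apd, -rng_apd, 2 * rng_apd, -2 * rng_apd):
        for tau_0 in (20.0, 60.0, 150.0):
            try:
                popt, _ = curve_fit(
                    _model, di, apd, p0=(apd.max(), a1_0, tau_0),
                    bounds=([-np.inf, -np.inf, 1.0], [np.inf, np.inf, 2000.0]),
                    maxfev=5000)
            except RuntimeError:
                continue
            resid = apd - _model(di, *popt)
            rms = math.sqrt(np.mean(resid ** 2))
            # ties at equal residual break toward the smallest tau1
            key = (round(rms, 9), popt[2])
            if best is None or key < best[0]:
                best = (key, popt, rms)
        # an essentially perfect fit cannot be improved; stop deterministically
        if best is not None and best[2] < 0.05:
            break
    if best is None:
        return None
    (y0, a1, tau1), rms = best[1], best[2]
    smax = abs(a1) / tau1 * math.exp(-di.min() / tau1)
    return RestitutionFit(data.node_id, float(y0), float(a1), float(tau1),
                          float(smax), float(abs(a1) / tau1), float(rms),
                          len(di))


@dataclass
class SmaxMaps:
    per_node: np.ndarray       # (n,) Smax, NaN for unfit nodes
    regional_mean: dict        # region_id -> mean Smax (NaN if no fit node)
    global_mean: float
    n_unfit: int


def smax_maps(fits, tissue: TissueModel) -> SmaxMaps:
    """Per-node / per-region / global mean Smax over fit nodes."""
    per_node = np.full(tissue.n_nodes, np.nan)
    for f in fits:
        if f is not None:
            per_node[f.node_id] = f.smax
    defined = np.isfinite(per_node)
    regional = {}
    for rid in np.unique(tissue.region_id):
        sel = (tissue.region_id == rid) & defined
        regional[int(rid)] = float(np.mean(per_node[sel])) if sel.any() else float("nan")
    global_mean = float(np.mean(per_node[defined])) if defined.any() else float("nan")
    n_unfit = int(tissue.active.sum() - defined.sum())
    return SmaxMaps(per_node, regional, global_mean, n_unfit)


def node_restitution_table(trace: SimulationTrace, tissue: TissueModel,
                           onset_ms: float | None, beats_after: int = 3,
                           node_ids=None):
    """Fit every requested node, limiting data to `beats_after` beats past
    the AF onset (per node).  Returns a list of RestitutionFit / None."""
    if node_ids is None:
        node_ids = np.flatnonzero(tissue.active)
    fits = []
    for node in node_ids:
        until = None
        if onset_ms is not None:
            v = trace.V[:, node].astype(float)
            beats = beat_features(trace.t, v, trace.activation_threshold,
                                  trace.activation_lockout)
            after = [b.upstroke for b in beats if b.upstroke > onset_ms]
            until = after[beats_after - 1] if len(after) >= beats_after else None
            if until is None and after:
                until = after[-1]
        data = extract_apd_di(trace, int(node), until)
        fits.append(fit_restitution(data))
    return fits


def fits_to_csv(fits, path):
    import pandas as pd
    rows = [dict(node_id=f.node_id, y0=f.y0, A1=f.a1, tau1=f.tau1,
                 smax=f.smax, rms=f.rms_residual, n_pairs=f.n_pairs)
            for f in fits if f is not None]
    pd.DataFrame(rows).to_csv(path, index=False)
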