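"""Dominant-frequency (DF) mapping.

Per-node DF is the frequency of the highest peak of the magnitude spectrum
of 6 s of membrane potential (mean-subtracted, Hann-tapered), searched in
0.5-20 Hz; the study windows are 16-22, 22-28 and 28-34 s after the start
of induction.  The "highest 5% of the DF area" is the node set whose DF is
within 5% of the window maximum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .monodomain import SimulationTrace
from .tissue import TissueModel

DEFAULT_WINDOWS = ((16.0, 22.0), (22.0, 28.0), (28.0, 34.0))
SEARCH_BAND = (0.5, 20.0)   # Hz
QUIESCENT_SPAN_MV = 10.0    # below this peak-to-peak the node has no APs


class DFError(ValueError):
    pass


@dataclass
class DFMap:
    windows: tuple             # ((start_s, end_s), ...)
    df: np.ndarray             # (n_nodes, n_windows) Hz, NaN where undefined
    resolution: float          # Hz (1 / window length)
    mean_df_per_window: np.ndarray   # (n_windows,)
    regional_df: dict          # region_id -> (n_windows,) means


def compute_df(v, dt_record_ms, band=SEARCH_BAND):
    """DF [Hz] of one node's potential segment; NaN for quiescent segments.

    Maximum magnitude-spectrum bin after mean removal and Hann taper,
    searched within `band`; argmax ties break toward lower frequency."""
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise DFError("non-finite samples in segment")
    if np.ptp(v) < QUIESCENT_SPAN_MV:
        return float("nan")
    x = (v - v.mean()) * np.hanning(v.size)
    mag = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(v.size, d=dt_record_ms / 1000.0)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    if not sel.any() or mag[sel].max() <= 0:
        return float("nan")
    return float(freqs[sel][np.argmax(mag[sel])])


def df_windows(trace: SimulationTrace, tissue: TissueModel,
               windows=DEFAULT_WINDOWS, band=SEARCH_BAND) -> DFMap:
    """Per-node DF for each analysis window plus window and regional means."""
    windows = tuple((float(a), float(b)) for a, b in windows)
    t_end = trace.t[-1]
    for a, b in windows:
        # a window may fall short of the trace end by at most one sample
        if b * 1000.0 > t_end + 1.001 * trace.dt_record:
            raise DFError(f"window {a}-{b} s exceeds the trace ({t_end/1000:.2f} s)")
    n = trace.n_nodes
    df = np.full((n, len(windows)), np.nan)
    active = tissue.active
    for w, (a, b) in enumerate(windows):
        i0 = int(round(a * 1000.0 / trace.dt_record))
        i1 = min(int(round(b * 1000.0 / trace.dt_record)), trace.V.shape[0])
        seg = trace.V[i0:i1]
        for k in np.flatnonzero(active):
            df[k, w] = compute_df(seg[:, k], trace.dt_record, band)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_df = np.nanmean(df, axis=0)
        regional = {}
        for rid in np.unique(tissue.region_id):
            sel = tissue.region_id == rid
            regional[int(rid)] = np.nanmean(df[sel], axis=0)
    res = 1.0 / (windows[0][1] - windows[0][0])
    return DFMap(windows, df, res, mean_df, regional)


def top_df_area(dfmap: DFMap, window_index: int, mode="value",
                fraction=0.05) -> np.ndarray:
    """Highest-DF node set for one window.

    mode="value" (default): all nodes with DF >= (1 - fraction) * max DF;
    mode="quantile": the top `fraction` of defined nodes by count."""
    col = dfmap.df[:, window_index]
    defined = np.isfinite(col)
    if not defined.any():
        raise DFError("all DFs undefined in this window")
    if mode == "value":
        thr = (1.0 - fraction) * np.nanmax(col)
        return np.flatnonzero(defined & (col >= thr))
    if mode == "quantile":
        k = max(1, int(np.ceil(fraction * defined.sum())))
        order = np.argsort(-np.where(defined, col, -np.inf), kind="stable")
        return np.sort(order[:k])
    raise DFError(f"unknown mode {mode!r}")


def dfmap_to_csv(dfmap: DFMap, path):
    import pandas as pd
    rows = []
    for w, (a, b) in enumerate(dfmap.windows):
        for node, val in enumerate(dfmap.df[:, w]):
            rows.append(dict(node_id=node, window=f"{a:g}-{b:g}s", df_hz=val))
    pd.DataFrame(rows).to_csv(path, index=False)
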