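"""Courtemanche-Ramirez-Nattel human atrial myocyte model with AF
electrical remodeling, exposed per node for the monodomain solver and as a
paced single cell for restitution work.

The AF-remodeled profile scales maximal conductances/fluxes:
IK1 x2.0, Na/Ca exchanger x1.4, INa x0.9, Ito x0.3, ICaL x0.5, IKur x0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import h5py

from . import _kernels
from ._kernels import N_STATE, rest_state  # noqa: F401  (re-exported)


class ConfigurationError(ValueError):
    pass


class IntegrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class RemodelingProfile:
    """Dimensionless multipliers on maximal conductances/fluxes."""
    ik1: float = 1.0
    incx: float = 1.0
    ina: float = 1.0
    ito: float = 1.0
    ical: float = 1.0
    ikur: float = 1.0

    def __post_init__(self):
        for name in ("ik1", "incx", "ina", "ito", "ical", "ikur"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"scale factor {name} must be >= 0")

    def as_array(self):
        return np.array([self.ik1, self.incx, self.ina, self.ito,
                         self.ical, self.ikur])

    def scaled(self, **factors):
        """Multiply selected factors, e.g. profile.scaled(ical=1.2)."""
        vals = {n: getattr(self, n) for n in
                ("ik1", "incx", "ina", "ito", "ical", "ikur")}
        for name, f in factors.items():
            vals[name] = vals[name] * f
        return RemodelingProfile(**vals)


AF_REMODELED = RemodelingProfile(ik1=2.0, incx=1.4, ina=0.9, ito=0.3,
                                 ical=0.5, ikur=0.5)


def make_profile(kind="control", **factors) -> RemodelingProfile:
    """control -> all ones; af_remodeled -> the chronic-AF scalings;
    custom -> explicit factors (ik1=, incx=, ina=, ito=, ical=, ikur=)."""
    if kind == "control":
        if factors:
            raise ConfigurationError("control profile takes no factors")
        return RemodelingProfile()
    if kind == "af_remodeled":
        if factors:
            raise ConfigurationError("af_remodeled profile takes no factors")
        return AF_REMODELED
    if kind == "custom":
        return RemodelingProfile(**factors)
    raise ConfigurationError(f"unknown profile kind {kind!r}")


_TABLE_CACHE: dict = {}


def tables_for(dt: float) -> np.ndarray:
    key = round(dt, 9)
    if key not in _TABLE_CACHE:
        _TABLE_CACHE[key] = _kernels.build_tables(dt)
    return _TABLE_CACHE[key]


def step_cell(state, profile: RemodelingProfile, i_stim=0.0, dt=0.02):
    """Advance a single cell state (length-21 vector) by dt [ms].

    i_stim is a depolarizing current density [pA/pF].  Raises
    IntegrationError when the state has diverged.
    """
    if dt > 0.05:
        raise ConfigurationError("dt must be <= 0.05 ms for the explicit scheme")
    S = np.asarray(state, dtype=float).reshape(1, N_STATE).copy()
    tab = tables_for(dt)
    status = _kernels.step_nodes(
        S, np.zeros(1), np.full(1, float(i_stim)),
        np.ones(1, dtype=bool), tab, dt, profile.as_array(),
        np.exp(-dt / _kernels.TAU_F_CA), np.exp(-dt / _kernels.TAU_U),
        np.zeros(1), np.zeros(1), np.zeros(1), True)
    if status != 0 or not np.all(np.isfinite(S)):
        raise IntegrationError("single-cell integration diverged (node 0)")
    return S[0]


def pace_cell(profile, cycle_length, n_beats, dt=0.02,
              stim_amplitude=40.0, stim_duration=2.0,
              pre_beats=20, pre_cl=600.0, record_dt=0.2,
              initial_state=None):
    """Pace a single cell: pre_beats at pre_cl, then n_beats at cycle_length.

    Returns (t [ms], V [mV]) recorded every record_dt over the final
    n_beats plus one trailing cycle for repolarization of the last beat.
    """
    if n_beats < 1:
        raise ConfigurationError("n_beats must be >= 1")
    S = (rest_state() if initial_state is None
         else np.asarray(initial_state, dtype=float)).reshape(1, N_STATE).copy()
    tab = tables_for(dt)

    stim_times = np.asarray(
        [k * pre_cl for k in range(pre_beats)]
        + [pre_beats * pre_cl + k * cycle_length for k in range(n_beats)])
    total = pre_beats * pre_cl + (n_beats + 1) * cycle_length
    n_steps = int(round(total / dt))
    rec_every = max(1, int(round(record_dt / dt)))
    n_rec = n_steps // rec_every + 1
    Vrec = np.empty((n_rec, 1), dtype=np.float32)
    zeros = np.zeros((1, 1))
    cmask = np.zeros((1, 1), dtype=bool)
    status, at_step = _kernels.run_monodomain(
        S, np.ones(1, dtype=bool), zeros, zeros, zeros, zeros,
        zeros, zeros, zeros, cmask, tab, dt, n_steps, rec_every, Vrec,
        stim_times, np.full(stim_times.size, float(stim_duration)),
        np.full(stim_times.size, float(stim_amplitude)),
        np.arange(stim_times.size + 1), np.zeros(stim_times.size, dtype=np.int64),
        profile.as_array(), 1, 1)
    if status != 0:
        raise IntegrationError(
            f"single-cell integration diverged at t={at_step * dt:.2f} ms (node 0)")
    t = np.arange(n_rec) * rec_every * dt - pre_beats * pre_cl
    keep = t >= 0
    return t[keep], Vrec[keep, 0].astype(float)


def apd90_singlecell(profile, cycle_length, n_beats=8, **kwargs):
    """APD90 [ms] of the last elicited beat under steady pacing.

    Returns None (induction failure) when no action potential is elicited,
    e.g. for a subthreshold stimulus.
    """
    if n_beats < 5:
        raise ConfigurationError("n_beats must be >= 5 to approach steady state")
    from .restitution import beat_features
    t, v = pace_cell(profile, cycle_length, n_beats, **kwargs)
    beats = beat_features(t, v)
    complete = [b for b in beats if b.apd90 is not None]
    if not complete:
        return None
    return complete[-1].apd90


def save_state(state, path):
    with h5py.File(path, "w") as fh:
        fh.create_dataset("state", data=np.asarray(state))


def load_state(path):
    with h5py.File(path, "r") as fh:
        return fh["state"][...]
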