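"""Cohort orchestration: a set of synthetic "patients" spanning a grid of
ionic scalings, each run through the full pipeline (substrate -> ramp
induction -> Smax map -> DF windows -> paired ablation arms), plus the
study-level summaries (regional DF-Smax Spearman correlation per window,
low/high-Smax stratification, per-arm defragmentation rates).

Inter-patient Smax/DF variation is created by scaling ICaL and IK1 around
the AF-remodeled profile: more ICaL lengthens the action potential and
steepens restitution (higher Smax, slower drivers); more IK1 shortens and
flattens it (lower Smax, faster drivers).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .ablation import ExperimentReport, run_ablation_experiment
from .dfmap import DEFAULT_WINDOWS, df_windows
from .ionic import make_profile
from .monodomain import SolverConfig
from .protocols import RampProtocol, induce_af
from .restitution import node_restitution_table, smax_maps
from .stats import contingency_test, mann_whitney, median_iqr, spearman
from .tissue import TissueConfig, generate_substrate

SMAX_CLASS_CUT = 1.0   # low: global Smax < 1, high: >= 1

# ionic-scaling grid endpoints (multipliers on the AF-remodeled profile).
# Only ICaL is varied: it steepens restitution (raises Smax) and lengthens
# APD without the conduction-velocity confound an IK1 co-variation brings.
ICAL_GRID = (0.55, 1.05)
IK1_GRID = (1.0, 1.0)


def default_cohort_tissue() -> TissueConfig:
    """Desk-scale AF substrate (38.4 x 18.8 mm sheet at 0.4 mm spacing).

    The upper two thirds hold a scar-anchored racetrack: a long linear scar
    strand with fibers wrapping it (`circuit` style), so a wave circulates
    around it as a protected macro-reentrant AF driver.  A scar pinch in
    the lower lane forms a narrow isthmus channel whose rate-dependent
    expansion block converts the final ramp beats into one-way circulation.
    A transverse scar line separates the driver compartment from an outer
    band (with two PV openings for CPVI) that the driver activates through
    a gap in that line; a low-voltage patch sits in the outer band."""
    return TissueConfig(
        nx=96, ny=48, spacing_um=400.0, n_samples=400,
        n_patches=2, patch_radius_mm=3.5, patch_depth=0.9,
        patch_centers_frac=((0.75, 0.372),),   # patch gates the divider gap
        fiber_style="circuit",
        scar_slots=(
            (0.12, 0.702, 0.88, 0.702, 0.8),    # core strand (racetrack)
            (0.0, 0.372, 0.70, 0.372, 0.8),     # divider, left section
            (0.80, 0.372, 1.0, 0.372, 0.8),     # divider, right section
            (0.25, 0.479, 0.35, 0.479, 2.0),    # isthmus pinch (diode)
        ),
        pv_radius_mm=1.0, pv_centers_frac=((0.15, 0.16), (0.85, 0.16)),
        n_regions=10)


def default_cohort_protocol() -> RampProtocol:
    from .protocols import PacingSite
    return RampProtocol(pacing_site=PacingSite(frac_x=0.45, frac_y=0.553,
                                               radius_mm=1.6),
                        stim_amplitude=60.0)


@dataclass
class CohortConfig:
    """Study conditions of the desk-scale cohort."""
    tissue: TissueConfig = field(default_factory=default_cohort_tissue)
    protocol: RampProtocol = field(default_factory=default_cohort_protocol)
    solver: SolverConfig = field(default_factory=lambda: SolverConfig(
        dt=0.075, diffusion_scale=0.8))
    observe_until_ms: float = 34000.0
    windows: tuple = DEFAULT_WINDOWS
    smax_node_stride: int = 3      # fit every stride-th active node
    run_arms: bool = True


@dataclass
class CohortRecord:
    model_id: int
    seed: int
    ical_scale: float
    ik1_scale: float
    induced: bool
    global_smax: float = float("nan")
    smax_class: str | None = None
    mean_df: np.ndarray | None = None            # per window
    regional_smax: dict = field(default_factory=dict)
    regional_df: dict = field(default_factory=dict)
    arm_reports: dict = field(default_factory=dict)  # arm -> ExperimentReport


def _model_profiles(n_models):
    lam = np.linspace(0.0, 1.0, n_models) if n_models > 1 else np.array([0.5])
    out = []
    for l in lam:
        ical = ICAL_GRID[0] + (ICAL_GRID[1] - ICAL_GRID[0]) * l
        ik1 = IK1_GRID[0] + (IK1_GRID[1] - IK1_GRID[0]) * l
        out.append((make_profile("af_remodeled").scaled(ical=ical, ik1=ik1),
                    ical, ik1))
    return out


def run_model(model_id, seed, profile, config: CohortConfig,
              ical_scale=1.0, ik1_scale=1.0) -> CohortRecord:
    """Full pipeline for one synthetic patient."""
    rec = CohortRecord(model_id, seed, ical_scale, ik1_scale, induced=False)
    tissue, _ = generate_substrate(config.tissue, seed=seed)
    result = induce_af(tissue, profile, config.protocol,
                       observe_until=config.observe_until_ms,
                       solver=config.solver)
    rec.induced = result.induced

    node_ids = np.flatnonzero(tissue.active)[::config.smax_node_stride]
    fits = node_restitution_table(result.trace, tissue, result.onset_time,
                                  node_ids=node_ids)
    smap = smax_maps(fits, tissue)
    rec.global_smax = smap.global_mean
    if np.isfinite(smap.global_mean):
        rec.smax_class = "low" if smap.global_mean < SMAX_CLASS_CUT else "high"
    rec.regional_smax = smap.regional_mean

    if not result.induced:
        return rec
    dfm = df_windows(result.trace, tissue, config.windows)
    rec.mean_df = dfm.mean_df_per_window
    rec.regional_df = dfm.regional_df

    if config.run_arms:
        for arm in ("cpvi_only", "cpvi_plus_df"):
            rec.arm_reports[arm] = run_ablation_experiment(
                tissue, profile, config.protocol, arm,
                solver=config.solver, baseline=result, dfmap=dfm)
    return rec


def run_cohort(n_models: int, config: CohortConfig | None = None,
               base_seed: int = 0, substrate_seeds=None,
               screen_max_tries: int = 1):
    """Run the cohort and summarize.  Deterministic for a fixed base_seed.

    Returns (records, summary).  Models that fail induction are recorded
    and excluded from the DF/ablation summaries (counted in the summary).

    substrate_seeds: optional explicit per-model substrate seeds (e.g. a
    pre-screened inducible-substrate library standing in for the enrolled
    AF population).  screen_max_tries > 1 screens derived seeds instead:
    each model retries fresh substrates until AF is induced or the budget
    is exhausted (the last attempt is recorded either way).
    """
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    config = config or CohortConfig()
    n_seeds = n_models * max(1, screen_max_tries)
    derived = np.random.SeedSequence(base_seed).generate_state(n_seeds) % (2 ** 31)
    records = []
    for m, (profile, ical, ik1) in enumerate(_model_profiles(n_models)):
        if substrate_seeds is not None:
            tries = [int(substrate_seeds[m])]
        else:
            tries = [int(derived[m * screen_max_tries + t])
                     for t in range(max(1, screen_max_tries))]
        rec = None
        for seed in tries:
            rec = run_model(m, seed, profile, config,
                            ical_scale=ical, ik1_scale=ik1)
            if rec.induced:
                break
        records.append(rec)
    return records, summarize_cohort(records, len(config.windows))


def regional_table(records):
    """Tidy rows (model_id, region_id, window, smax, df) over induced models."""
    rows = []
    for rec in records:
        if not rec.induced:
            continue
        for rid, s in rec.regional_smax.items():
            dfv = rec.regional_df.get(rid)
            if dfv is None:
                continue
            for w, d in enumerate(np.atleast_1d(dfv)):
                rows.append(dict(model_id=rec.model_id, region_id=rid,
                                 window=w, smax=s, df=d))
    return rows


def summarize_cohort(records, n_windows=3):
    """Study-level summary: per-window regional Spearman rho(DF, Smax),
    class-stratified DF comparison, per-class defragmentation rates."""
    summary = {
        "n_models": len(records),
        "n_induced": sum(r.induced for r in records),
        "n_failed_induction": sum(not r.induced for r in records),
        "warnings": [],
    }
    rows = regional_table(records)
    rho = {}
    for w in range(n_windows):
        pts = [(r["smax"], r["df"]) for r in rows
               if r["window"] == w and np.isfinite(r["smax"]) and np.isfinite(r["df"])]
        if len(pts) >= 3:
            s, d = zip(*pts)
            rho[w] = spearman(s, d)
        else:
            rho[w] = (float("nan"), float("nan"))
            summary["warnings"].append(f"too few regions for window {w} correlation")
    summary["regional_spearman"] = rho

    low = [r for r in records if r.induced and r.smax_class == "low"]
    high = [r for r in records if r.induced and r.smax_class == "high"]
    strat = {}
    for w in range(n_windows):
        lo = [r.mean_df[w] for r in low if r.mean_df is not None]
        hi = [r.mean_df[w] for r in high if r.mean_df is not None]
        cell = {"low_median_iqr": median_iqr(lo), "high_median_iqr": median_iqr(hi)}
        if lo and hi:
            cell["mw_p"] = mann_whitney(lo, hi)[1]
        strat[w] = cell
    summary["df_by_smax_class"] = strat
    summary["smax_by_class"] = {
        "low": median_iqr([r.global_smax for r in low]),
        "high": median_iqr([r.global_smax for r in high]),
    }

    rates = {}
    for cls, group in (("low", low), ("high", high), ("all", low + high)):
        cell = {}
        for arm in ("cpvi_only", "cpvi_plus_df"):
            reps = [r.arm_reports.get(arm) for r in group]
            reps = [p for p in reps if p is not None and not p.skipped]
            cell[arm] = {
                "n": len(reps),
                "n_defrag": sum(bool(p.defragmentation) for p in reps),
            }
        rates[cls] = cell
    summary["defragmentation"] = rates
    if not low or not high:
        summary["warnings"].append("single-class cohort: stratified rows incomplete")
    return summary


def records_to_csv(records, path):
    import pandas as pd
    pd.DataFrame(regional_table(records)).to_csv(path, index=False)


def summary_to_json(summary, path):
    import json

    def clean(obj):
        if isinstance(obj, dict):
            return {str(k): clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [clean(v) for v in obj]
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return obj

    with open(path, "w") as fh:
        json.dump(clean(summary), fh, indent=2)
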