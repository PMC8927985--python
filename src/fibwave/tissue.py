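"""Synthetic atrial substrate.

Builds a 2D sheet standing in for a clinical left-atrial electroanatomical
map: a spatially correlated bipolar-voltage field with low-voltage patches,
scattered catheter-style sample points, inverse-distance-weighted (IDW)
interpolation of those samples onto the grid, a voltage-to-fibrosis
probability map, per-node anisotropic conductivities, a smooth fiber
orientation field, circular pulmonary-vein (PV) openings, and an
equal-area region partition for regional summaries.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
import h5py
import yaml
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

# Tissue conductivities [S/m]: longitudinal / transverse for nonfibrotic
# and fibrotic nodes (anisotropy ratio ~5:1).
SIGMA_L_NONFIB = 0.1264
SIGMA_L_FIB = 0.0546
SIGMA_T_NONFIB = 0.0252
SIGMA_T_FIB = 0.0068

FIBROSIS_VOLTAGE_CUTOFF = 1.74  # mV; above this the fibrosis probability is 0


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class SamplePoint:
    """A catheter-style voltage sample: position [mm], bipolar amplitude [mV]."""
    position: tuple
    amplitude: float

    def __post_init__(self):
        if not np.all(np.isfinite(self.position)):
            raise ConfigurationError("sample position must be finite")
        if self.amplitude < 0:
            raise ConfigurationError("bipolar amplitude must be >= 0")


@dataclass
class TissueConfig:
    """Parameters of the synthetic substrate generator (the `tissue:` YAML block)."""
    nx: int = 60
    ny: int = 60
    spacing_um: float = 300.0
    n_samples: int = 500
    n_patches: int = 3
    patch_radius_mm: float = 6.0
    patch_depth: float = 0.8          # fractional voltage depression at patch center
    healthy_voltage_mv: tuple = (1.8, 2.4)  # background range, above the fibrosis cutoff
    voltage_smooth_mm: float = 6.0
    fiber_style: str = "wavy"         # uniform | wavy | random_smooth
    n_regions: int = 10
    pv_radius_mm: float = 4.0
    pv_centers_frac: tuple = ((0.28, 0.72), (0.72, 0.72), (0.28, 0.28), (0.72, 0.28))
    idw_power: float = 2.0
    idw_radius_mm: float = 10.0
    fibrosis_mode: str = "sample"     # sample | threshold
    fibrosis_threshold: float = 0.5
    # linear non-conducting scar strands: (fx0, fy0, fx1, fy1, halfwidth_mm)
    # in fractional sheet coordinates; empty by default
    scar_slots: tuple = ()
    # optional deterministic low-voltage patch centers (fractional coords);
    # remaining patches up to n_patches are placed randomly
    patch_centers_frac: tuple = ()

    def validate(self):
        if self.nx <= 0 or self.ny <= 0 or self.spacing_um <= 0:
            raise ConfigurationError("grid dimensions and spacing must be positive")
        if self.n_samples < 1:
            raise ConfigurationError("need at least one sample point")
        if self.n_regions < 1:
            raise ConfigurationError("n_regions must be >= 1")
        if self.fiber_style not in ("uniform", "wavy", "random_smooth",
                                    "circumferential", "circuit"):
            raise ConfigurationError(f"unknown fiber_style {self.fiber_style!r}")
        if self.fibrosis_mode not in ("sample", "threshold"):
            raise ConfigurationError(f"unknown fibrosis_mode {self.fibrosis_mode!r}")

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        block = doc.get("tissue", doc) if isinstance(doc, dict) else {}
        known = {f.name for f in dataclasses.fields(cls)}
        kwargs = {}
        for key, val in block.items():
            if key == "seed":
                continue
            if key not in known:
                raise ConfigurationError(f"unknown tissue option {key!r}")
            kwargs[key] = tuple(map(tuple, val)) if key == "pv_centers_frac" else (
                tuple(val) if isinstance(val, list) else val)
        return cls(**kwargs)


@dataclass
class TissueModel:
    """Discretized sheet with per-node electrophysiological substrate."""
    nx: int
    ny: int
    spacing_um: float
    node_coords: np.ndarray        # (n, 2) [mm]
    fiber_angle: np.ndarray        # (n,) [rad]
    voltage: np.ndarray            # (n,) interpolated bipolar amplitude [mV]
    fibrosis: np.ndarray           # (n,) bool
    sigma_L: np.ndarray            # (n,) [S/m]
    sigma_T: np.ndarray            # (n,) [S/m]
    region_id: np.ndarray          # (n,) int in 1..R
    pv_openings: list              # [(cx_mm, cy_mm, radius_mm), ...]
    void: np.ndarray               # (n,) bool, PV-opening nodes (no tissue)
    ablated: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.ablated is None:
            self.ablated = np.zeros(self.n_nodes, dtype=bool)

    @property
    def n_nodes(self):
        return self.nx * self.ny

    @property
    def spacing_mm(self):
        return self.spacing_um / 1000.0

    @property
    def active(self):
        """Nodes that carry tissue and conduct (not void, not ablated)."""
        return ~self.void & ~self.ablated

    def copy(self):
        return TissueModel(
            self.nx, self.ny, self.spacing_um,
            self.node_coords.copy(), self.fiber_angle.copy(),
            self.voltage.copy(), self.fibrosis.copy(),
            self.sigma_L.copy(), self.sigma_T.copy(), self.region_id.copy(),
            list(self.pv_openings), self.void.copy(), self.ablated.copy())

    def save(self, path):
        with h5py.File(path, "w") as fh:
            for name in ("node_coords", "fiber_angle", "voltage", "fibrosis",
                         "sigma_L", "sigma_T", "region_id", "void", "ablated"):
                fh.create_dataset(name, data=getattr(self, name))
            fh.create_dataset("pv_openings", data=np.asarray(self.pv_openings, dtype=float))
            fh.attrs["nx"] = self.nx
            fh.attrs["ny"] = self.ny
            fh.attrs["spacing_um"] = self.spacing_um

    @classmethod
    def load(cls, path):
        with h5py.File(path, "r") as fh:
            arrays = {name: fh[name][...] for name in
                      ("node_coords", "fiber_angle", "voltage", "fibrosis",
                       "sigma_L", "sigma_T", "region_id", "void", "ablated")}
            pv = [tuple(row) for row in fh["pv_openings"][...]]
            return cls(int(fh.attrs["nx"]), int(fh.attrs["ny"]),
                       float(fh.attrs["spacing_um"]),
                       arrays["node_coords"], arrays["fiber_angle"],
                       arrays["voltage"], arrays["fibrosis"].astype(bool),
                       arrays["sigma_L"], arrays["sigma_T"],
                       arrays["region_id"].astype(int), pv,
                       arrays["void"].astype(bool), arrays["ablated"].astype(bool))


def fibrosis_probability(x):
    """Probability that a node with bipolar voltage x [mV] is fibrotic.

    Piecewise: 1 at x = 0; the cubic -40.0 x^3 + 155 x^2 - 206 x + 99.8
    (a percentage, divided by 100) on 0 < x <= 1.74; 0 above 1.74 mV.
    The result is clamped to [0, 1].
    """
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise ValueError("bipolar voltage must be >= 0 mV")
    cubic = (-40.0 * arr ** 3 + 155.0 * arr ** 2 - 206.0 * arr + 99.8) / 100.0
    p = np.where(arr == 0.0, 1.0,
                 np.where(arr > FIBROSIS_VOLTAGE_CUTOFF, 0.0, np.clip(cubic, 0.0, 1.0)))
    return float(p) if np.isscalar(x) else p


def assign_fibrosis(probabilities, seed, mode="sample", threshold=0.5):
    """Realize per-node yes/no fibrosis from per-node probabilities.

    mode="sample": seeded Bernoulli draw per node (default);
    mode="threshold": deterministic cut at `threshold`.
    """
    p = np.asarray(probabilities, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    if mode == "threshold":
        return p >= threshold
    rng = np.random.default_rng(seed)
    return rng.random(p.shape) < p


def assign_conductivity(tissue: TissueModel) -> TissueModel:
    """Set each node's (sigma_L, sigma_T) from its fibrosis flag (in place)."""
    fib = tissue.fibrosis
    tissue.sigma_L = np.where(fib, SIGMA_L_FIB, SIGMA_L_NONFIB)
    tissue.sigma_T = np.where(fib, SIGMA_T_FIB, SIGMA_T_NONFIB)
    return tissue


def idw_interpolate(points, targets, power=2.0, radius=10.0):
    """Inverse-distance-weighted interpolation of scattered samples.

    Each target gets the d^-power weighted mean of sample amplitudes within
    `radius` [mm]; a target coincident with a sample returns that sample's
    amplitude exactly.  Returns (values, missing) where `missing` flags
    targets with no in-radius sample (value NaN there).
    """
    if power <= 0 or radius <= 0:
        raise ConfigurationError("IDW power and radius must be positive")
    pos = np.asarray([p.position for p in points], dtype=float)
    amp = np.asarray([p.amplitude for p in points], dtype=float)
    tgt = np.asarray(targets, dtype=float)
    tree = cKDTree(pos)
    neighbors = tree.query_ball_point(tgt, r=radius)
    values = np.full(len(tgt), np.nan)
    missing = np.zeros(len(tgt), dtype=bool)
    for i, idx in enumerate(neighbors):
        if not idx:
            missing[i] = True
            continue
        d = np.linalg.norm(pos[idx] - tgt[i], axis=1)
        hit = d < 1e-12
        if np.any(hit):
            values[i] = amp[np.asarray(idx)[hit][0]]
            continue
        w = d ** (-power)
        values[i] = np.sum(w * amp[idx]) / np.sum(w)
    return values, missing


def _region_grid_shape(n_regions, nx, ny):
    """Factor R into (rows, cols) best matching the sheet aspect ratio."""
    best = None
    for rows in range(1, n_regions + 1):
        if n_regions % rows:
            continue
        cols = n_regions // rows
        cost = abs(cols / rows - nx / ny)
        if best is None or cost < best[0]:
            best = (cost, rows, cols)
    return best[1], best[2]


def partition_regions(nx, ny, n_regions):
    """Equal-area rectangular-block partition; labels 1..R, every node labeled."""
    rows, cols = _region_grid_shape(n_regions, nx, ny)
    row_edges = np.linspace(0, ny, rows + 1).astype(int)
    col_edges = np.linspace(0, nx, cols + 1).astype(int)
    region = np.empty((ny, nx), dtype=int)
    label = 1
    for r in range(rows):
        for c in range(cols):
            region[row_edges[r]:row_edges[r + 1], col_edges[c]:col_edges[c + 1]] = label
            label += 1
    return region.reshape(-1)


def _fiber_field(config, rng, xx, yy, lx, ly, pv=(), slots=()):
    if config.fiber_style == "uniform":
        return np.zeros_like(xx)
    if config.fiber_style == "wavy":
        return 0.45 * np.sin(2 * np.pi * xx / lx) * np.cos(2 * np.pi * yy / ly)
    if config.fiber_style == "circuit":
        # fibers tangent to iso-distance contours around the FIRST scar
        # strand: conduction is longitudinal all the way around the circuit,
        # mimicking fiber tracts wrapping a linear scar
        if not slots:
            return np.zeros_like(xx)
        d = np.full(xx.shape, np.inf)
        for fx0, fy0, fx1, fy1, hw in slots[:1]:
            p0 = np.array([fx0 * lx, fy0 * ly])
            seg = np.array([fx1 * lx, fy1 * ly]) - p0
            rx = xx - p0[0]
            ry = yy - p0[1]
            t_par = np.clip((rx * seg[0] + ry * seg[1]) / max(seg @ seg, 1e-12),
                            0.0, 1.0)
            d = np.minimum(d, np.hypot(rx - t_par * seg[0], ry - t_par * seg[1]))
        gy, gx = np.gradient(gaussian_filter(d, sigma=2.0, mode="nearest"))
        theta = np.arctan2(gy, gx) + np.pi / 2
        return (theta + np.pi / 2) % np.pi - np.pi / 2
    if config.fiber_style == "circumferential":
        # fibers tangent to the nearest PV opening, as at real PV ostia
        if not pv:
            return np.zeros_like(xx)
        centers = np.asarray([(cx, cy) for cx, cy, _ in pv])
        dx = xx[..., None] - centers[:, 0]
        dy = yy[..., None] - centers[:, 1]
        d = np.hypot(dx, dy)
        nearest = np.argmin(d, axis=-1)
        ii, jj = np.indices(xx.shape)
        theta = np.arctan2(dy[ii, jj, nearest], dx[ii, jj, nearest]) + np.pi / 2
        # fold into (-pi/2, pi/2]: orientation, not direction
        return (theta + np.pi / 2) % np.pi - np.pi / 2
    noise = rng.standard_normal(xx.shape)
    smooth = gaussian_filter(noise, sigma=max(xx.shape) / 8, mode="reflect")
    smooth /= max(np.abs(smooth).max(), 1e-12)
    return (np.pi / 3) * smooth


def _voltage_field(config, rng, xx, yy):
    """Smooth background in the healthy range, depressed by low-voltage patches."""
    dx_mm = config.spacing_um / 1000.0
    noise = rng.standard_normal(xx.shape)
    smooth = gaussian_filter(noise, sigma=config.voltage_smooth_mm / dx_mm, mode="reflect")
    span = smooth.max() - smooth.min()
    u = (smooth - smooth.min()) / (span if span > 0 else 1.0)
    lo, hi = config.healthy_voltage_mv
    fieldv = lo + (hi - lo) * u
    lx, ly = xx.max(), yy.max()
    pad = config.patch_radius_mm * 0.5
    centers = [(fx * lx, fy * ly) for fx, fy in config.patch_centers_frac]
    while len(centers) < config.n_patches:
        centers.append((rng.uniform(pad, lx - pad), rng.uniform(pad, ly - pad)))
    for cx, cy in centers[:max(config.n_patches, len(centers))]:
        depth = config.patch_depth * rng.uniform(0.85, 1.1)
        r2 = (xx - cx) ** 2 + (yy - cy) ** 2
        fieldv = fieldv * (1.0 - np.clip(depth, 0.0, 0.97)
                           * np.exp(-r2 / config.patch_radius_mm ** 2))
    return np.clip(fieldv, 0.0, None)


def generate_substrate(config: TissueConfig, seed: int):
    """Generate a seeded synthetic substrate.

    Returns (TissueModel, [SamplePoint]).  The ground-truth voltage field is
    subsampled at scattered points and re-interpolated onto the grid by IDW,
    mimicking catheter mapping; fibrosis is realized from the voltage map and
    conductivities assigned from the fibrosis flags.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    nx, ny = config.nx, config.ny
    dx = config.spacing_um / 1000.0
    x = np.arange(nx) * dx
    y = np.arange(ny) * dx
    xx, yy = np.meshgrid(x, y)
    coords = np.column_stack([xx.reshape(-1), yy.reshape(-1)])
    lx, ly = x[-1], y[-1]

    # PV openings: node voids
    pv = [(fx * lx, fy * ly, config.pv_radius_mm) for fx, fy in config.pv_centers_frac]
    void = np.zeros(nx * ny, dtype=bool)
    for cx, cy, r in pv:
        void |= (coords[:, 0] - cx) ** 2 + (coords[:, 1] - cy) ** 2 < r ** 2
    # linear scar strands: distance from node to segment below halfwidth
    for fx0, fy0, fx1, fy1, hw in config.scar_slots:
        p0 = np.array([fx0 * lx, fy0 * ly])
        seg = np.array([fx1 * lx, fy1 * ly]) - p0
        rel = coords - p0
        t_par = np.clip(rel @ seg / max(seg @ seg, 1e-12), 0.0, 1.0)
        dist = np.linalg.norm(rel - t_par[:, None] * seg, axis=1)
        void |= dist < hw

    truth = _voltage_field(config, rng, xx, yy).reshape(-1)

    # catheter-style subsampling of the true field
    candidates = np.flatnonzero(~void)
    if candidates.size < max(4, 0.3 * nx * ny):
        raise ConfigurationError(
            "PV openings cover most of the sheet; shrink pv_radius_mm "
            "or enlarge the grid")
    n_samples = min(config.n_samples, candidates.size)
    chosen = rng.choice(candidates, size=n_samples, replace=False)
    samples = [SamplePoint(tuple(coords[k]), float(truth[k])) for k in chosen]

    voltage, missing = idw_interpolate(samples, coords,
                                       power=config.idw_power,
                                       radius=config.idw_radius_mm)
    if np.any(missing):
        # out-of-coverage nodes fall back to the nearest sample
        pos = np.asarray([p.position for p in samples])
        amp = np.asarray([p.amplitude for p in samples])
        _, nearest = cKDTree(pos).query(coords[missing])
        voltage[missing] = amp[nearest]

    p_fib = fibrosis_probability(voltage)
    fibrosis = assign_fibrosis(p_fib, seed=rng.integers(2 ** 31),
                               mode=config.fibrosis_mode,
                               threshold=config.fibrosis_threshold)
    fibrosis &= ~void

    angle = _fiber_field(config, rng, xx, yy, lx, ly, pv,
                         config.scar_slots).reshape(-1)
    region = partition_regions(nx, ny, config.n_regions)

    tissue = TissueModel(nx, ny, config.spacing_um, coords, angle, voltage,
                         fibrosis, np.empty(nx * ny), np.empty(nx * ny),
                         region, pv, void)
    assign_conductivity(tissue)
    return tissue, samples


def samples_to_csv(samples, path):
    import pandas as pd
    pd.DataFrame({
        "x_mm": [s.position[0] for s in samples],
        "y_mm": [s.position[1] for s in samples],
        "amplitude_mV": [s.amplitude for s in samples],
    }).to_csv(path, index=False)
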