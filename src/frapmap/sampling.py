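"""Numerical evaluation of photobleach-point sampling strategies.

How should a limited budget of FRAP measurement points (a few tens per
cell) be placed so that the reconstructed whole-cell diffusivity map is
accurate?  This module builds ground-truth diffusivity fields on masked
cell geometries (radial gradients and stepwise concentric patterns),
places measurement points either by an isotropic Gaussian of width sigma
centered in the cell or on a square lattice, reconstructs the field with
the variogram + SGS pipeline, and scores the reconstruction with MAE and
RMSE.  Pattern width is normalized by the equivalent cell radius
R_cell = sqrt(area / pi).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .exceptions import ValidationError
from .kriging import krige_map
from .sgs import SimulationGrid, derive_seeds, normal_score, run_ensemble
from .synthetic import sample_points_from_field
from .variogram import PointSamples, fit_exponential, semivariogram_cloud

__all__ = [
    "GroundTruthField",
    "SamplingPattern",
    "SweepResult",
    "ellipse_mask",
    "crescent_mask",
    "make_radial_field",
    "make_stepwise_field",
    "equivalent_radius",
    "gaussian_sampling",
    "lattice_sampling",
    "error_metrics",
    "reconstruct_sgs",
    "reconstruct_ok",
    "sweep_sigma",
    "sweep_npoints",
    "plateau_onset",
]


# --------------------------------------------------------------------------
# built-in cell geometries
# --------------------------------------------------------------------------

def ellipse_mask(shape=(140, 140), pixel_size: float = 0.5, semiaxes=(27.0, 24.0)):
    """Rounded cell: an axis-aligned ellipse centered in the image (um units)."""
    nrow, ncol = shape
    cy, cx = (nrow - 1) / 2.0 * pixel_size, (ncol - 1) / 2.0 * pixel_size
    y = np.arange(nrow) * pixel_size
    x = np.arange(ncol) * pixel_size
    X, Y = np.meshgrid(x, y)
    ax, ay = semiaxes
    return ((X - cx) / ax) ** 2 + ((Y - cy) / ay) ** 2 <= 1.0


def crescent_mask(shape=(140, 140), pixel_size: float = 0.5):
    """Elongated crescent cell: a long ellipse with a lobe carved out."""
    nrow, ncol = shape
    cy, cx = (nrow - 1) / 2.0 * pixel_size, (ncol - 1) / 2.0 * pixel_size
    y = np.arange(nrow) * pixel_size
    x = np.arange(ncol) * pixel_size
    X, Y = np.meshgrid(x, y)
    body = ((X - cx) / 33.0) ** 2 + ((Y - cy) / 14.0) ** 2 <= 1.0
    bite = ((X - cx) / 26.0) ** 2 + ((Y - (cy - 12.0)) / 9.0) ** 2 <= 1.0
    return body & ~bite


# --------------------------------------------------------------------------
# ground-truth fields
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GroundTruthField:
    """Known diffusivity values on the masked grid nodes."""

    values: np.ndarray
    kind: str
    params: dict

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if np.any(v <= 0):
            raise ValidationError("diffusivity values must be positive")
        object.__setattr__(self, "values", v)


def _radial_distance(grid: SimulationGrid):
    centroid = grid.nodes.mean(axis=0)
    return np.linalg.norm(grid.nodes - centroid, axis=1)


def make_radial_field(
    grid: SimulationGrid, D_center: float = 0.5, D_edge: float = 2.0
) -> GroundTruthField:
    """Linear radial gradient: D_center at the centroid rising (or falling)
    linearly with normalized radial distance to D_edge at the farthest node."""
    if D_center <= 0 or D_edge <= 0:
        raise ValidationError("diffusivities must be positive")
    if grid.n_nodes < 2:
        raise ValidationError("degenerate mask: need more than one node")
    d = _radial_distance(grid)
    vals = D_center + (D_edge - D_center) * d / d.max()
    return GroundTruthField(values=vals, kind="radial", params={"D_center": D_center, "D_edge": D_edge})


def make_stepwise_field(grid: SimulationGrid, levels, n_rings: int | None = None) -> GroundTruthField:
    """Concentric stepwise field: discrete jumps between rings of equal
    radial-distance quantiles, innermost ring taking levels[0]."""
    levels = np.asarray(levels, dtype=float)
    if n_rings is None:
        n_rings = levels.size
    if n_rings != levels.size or n_rings < 1:
        raise ValidationError("need one level per ring")
    if np.any(levels <= 0):
        raise ValidationError("levels must be positive")
    d = _radial_distance(grid)
    edges = np.quantile(d, np.linspace(0, 1, n_rings + 1)[1:-1]) if n_rings > 1 else np.array([])
    ring = np.digitize(d, edges, right=True)  # d <= edge stays in the inner ring
    return GroundTruthField(values=levels[ring], kind="stepwise", params={"levels": levels.tolist()})


def equivalent_radius(mask_or_grid, pixel_size: float | None = None) -> float:
    """Equivalent cell radius R_cell = sqrt(area / pi)."""
    if isinstance(mask_or_grid, SimulationGrid):
        area = mask_or_grid.n_nodes * mask_or_grid.pitch[0] * mask_or_grid.pitch[1]
    else:
        mask = np.asarray(mask_or_grid) != 0
        if not mask.any():
            raise ValidationError("empty mask")
        if pixel_size is None or pixel_size <= 0:
            raise ValidationError("pixel_size required for a raster mask")
        area = mask.sum() * pixel_size**2
    return float(np.sqrt(area / np.pi))


# --------------------------------------------------------------------------
# sampling patterns
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SamplingPattern:
    kind: str
    param: float  # sigma (gaussian) or spacing (lattice), um
    positions: np.ndarray
    seed: int | None = None

    @property
    def n_points(self) -> int:
        return self.positions.shape[0]


_tree_cache: dict = {}


def _node_tree(grid: SimulationGrid) -> cKDTree:
    key = id(grid)
    tree = _tree_cache.get(key)
    if tree is None:
        _tree_cache.clear()  # keep at most one grid's tree alive
        tree = _tree_cache[key] = cKDTree(grid.nodes)
    return tree


def _inside(grid: SimulationGrid, pts: np.ndarray) -> np.ndarray:
    """Membership test: within half a grid pitch of a masked-in node."""
    d, idx = _node_tree(grid).query(pts)
    dx = np.abs(pts[:, 0] - grid.nodes[idx, 0])
    dy = np.abs(pts[:, 1] - grid.nodes[idx, 1])
    return (dx <= grid.pitch[0] / 2 + 1e-9) & (dy <= grid.pitch[1] / 2 + 1e-9)


def gaussian_sampling(
    grid: SimulationGrid,
    sigma: float,
    n_points: int = 30,
    seed: int | None = None,
    min_spacing: float = 10.0,
    max_attempts: int = 200_000,
) -> SamplingPattern:
    """Draw measurement points from an isotropic Gaussian at the cell centroid.

    Candidates are rejection-sampled into the mask with a minimum pairwise
    spacing (the experimental protocol keeps bleach spots well separated).
    Raises a capacity error, reporting the achieved count, if the mask
    cannot hold ``n_points`` at the requested spacing within the attempt
    budget.
    """
    if sigma <= 0:
        raise ValidationError("sigma must be positive")
    rng = np.random.default_rng(seed)
    centroid = grid.nodes.mean(axis=0)
    accepted: list[np.ndarray] = []
    attempts = 0
    batch = 256
    while len(accepted) < n_points and attempts < max_attempts:
        cand = centroid + rng.normal(0.0, sigma, size=(batch, 2))
        attempts += batch
        ok = _inside(grid, cand)
        for p in cand[ok]:
            if len(accepted) >= n_points:
                break
            if min_spacing > 0 and accepted:
                if np.min(np.linalg.norm(np.array(accepted) - p, axis=1)) < min_spacing:
                    continue
            accepted.append(p)
    if len(accepted) < n_points:
        raise ValidationError(
            f"could not place {n_points} points at spacing {min_spacing} um "
            f"(achieved {len(accepted)})"
        )
    return SamplingPattern(kind="gaussian", param=float(sigma),
                           positions=np.array(accepted), seed=seed)


def lattice_sampling(grid: SimulationGrid, spacing: float) -> SamplingPattern:
    """Square lattice anchored at the cell centroid, clipped to the mask."""
    if spacing <= 0:
        raise ValidationError("spacing must be positive")
    centroid = grid.nodes.mean(axis=0)
    lo = grid.nodes.min(axis=0)
    hi = grid.nodes.max(axis=0)
    nx = int(np.ceil((hi[0] - lo[0]) / spacing)) + 1
    ny = int(np.ceil((hi[1] - lo[1]) / spacing)) + 1
    ix = np.arange(-nx, nx + 1)
    iy = np.arange(-ny, ny + 1)
    X, Y = np.meshgrid(centroid[0] + ix * spacing, centroid[1] + iy * spacing)
    pts = np.column_stack([X.ravel(), Y.ravel()])
    pts = pts[_inside(grid, pts)]
    return SamplingPattern(kind="lattice", param=float(spacing), positions=pts)


# --------------------------------------------------------------------------
# reconstruction and error metrics
# --------------------------------------------------------------------------

def error_metrics(truth, estimate) -> dict:
    """MAE and RMSE between two node-value vectors on the same node set."""
    truth = np.asarray(truth, dtype=float)
    estimate = np.asarray(estimate, dtype=float)
    if truth.shape != estimate.shape:
        raise ValidationError("truth and estimate are on different node sets")
    err = estimate - truth
    return {"mae": float(np.mean(np.abs(err))), "rmse": float(np.sqrt(np.mean(err**2)))}


def reconstruct_sgs(
    points: PointSamples,
    grid: SimulationGrid,
    n_real: int = 50,
    master_seed: int = 0,
    k_neighbors: int = 24,
):
    """Normal-score + variogram + SGS-ensemble reconstruction.

    Returns (mean node values in original units, SgsEnsemble).  A dataset
    with no resolvable value spread reconstructs as a constant map.
    """
    if np.ptp(points.z) == 0:
        return np.full(grid.n_nodes, points.z[0]), None
    scores, ns_map = normal_score(points.z)
    ns_points = PointSamples(u=points.u, z=scores)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = fit_exponential(semivariogram_cloud(ns_points))
    if model.c == 0:
        return np.full(grid.n_nodes, float(np.mean(points.z))), None
    ens = run_ensemble(
        ns_points, model, grid, n_real=n_real, master_seed=master_seed,
        k_neighbors=k_neighbors, normal_score_map=ns_map, value_floor=0.0,
    )
    return ens.mean_values, ens


def reconstruct_ok(points: PointSamples, grid: SimulationGrid):
    """Plain ordinary-kriging reconstruction (raw-space variogram fit)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = fit_exponential(semivariogram_cloud(points))
    if model.c == 0:
        return np.full(grid.n_nodes, float(np.mean(points.z)))
    est_map, _ = krige_map(points, model, grid)
    return est_map[grid.mask]


# --------------------------------------------------------------------------
# sweeps
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SweepResult:
    """Per-sweep-value error statistics (mean and SD over repeats)."""

    sweep_values: np.ndarray  # sigma/R_cell or n_points, ascending
    mae_mean: np.ndarray
    mae_sd: np.ndarray
    rmse_mean: np.ndarray
    rmse_sd: np.ndarray
    n_repeats: int
    master_seed: int
    label: str = "sigma_over_R"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                self.label: self.sweep_values,
                "mae_mean": self.mae_mean,
                "mae_sd": self.mae_sd,
                "rmse_mean": self.rmse_mean,
                "rmse_sd": self.rmse_sd,
                "n_repeats": self.n_repeats,
            }
        )


def sweep_sigma(
    grid: SimulationGrid,
    field: GroundTruthField,
    sigma_over_R_list,
    n_points: int = 30,
    repeats: int = 20,
    master_seed: int = 0,
    n_real: int = 50,
    min_spacing: float | None = None,
) -> SweepResult:
    """Reconstruction error versus Gaussian pattern width sigma / R_cell.

    For each sweep value: place ``n_points`` Gaussian-pattern points, sample
    the ground truth, reconstruct with the SGS pipeline, and score MAE/RMSE
    against the truth; aggregated over ``repeats`` with derived seeds.
    ``min_spacing`` defaults to one grid pitch (narrow patterns cannot honor
    the experimental ~10 um spacing).
    """
    svals = np.sort(np.asarray(sigma_over_R_list, dtype=float))
    R = equivalent_radius(grid)
    if min_spacing is None:
        min_spacing = min(grid.pitch)
    seeds = derive_seeds(master_seed, svals.size * repeats).reshape(svals.size, repeats)
    mae = np.empty((svals.size, repeats))
    rmse = np.empty((svals.size, repeats))
    for i, s in enumerate(svals):
        for rep in range(repeats):
            seed = int(seeds[i, rep])
            pattern = gaussian_sampling(
                grid, sigma=s * R, n_points=n_points, seed=seed, min_spacing=min_spacing
            )
            pts = sample_points_from_field(field.values, grid, pattern.positions)
            est, _ = reconstruct_sgs(pts, grid, n_real=n_real, master_seed=seed)
            m = error_metrics(field.values, est)
            mae[i, rep] = m["mae"]
            rmse[i, rep] = m["rmse"]
    return SweepResult(
        sweep_values=svals,
        mae_mean=mae.mean(axis=1), mae_sd=mae.std(axis=1),
        rmse_mean=rmse.mean(axis=1), rmse_sd=rmse.std(axis=1),
        n_repeats=repeats, master_seed=int(master_seed),
    )


def plateau_onset(sweep: SweepResult, tol: float = 0.10) -> float:
    """First sweep value whose mean MAE is within ``tol`` of the sweep minimum."""
    mmin = sweep.mae_mean.min()
    ok = sweep.mae_mean <= (1.0 + tol) * mmin
    return float(sweep.sweep_values[np.argmax(ok)])


def sweep_npoints(
    grid: SimulationGrid,
    field: GroundTruthField,
    n_list,
    sigma_over_R: float = 0.56,
    method: str = "sgs",
    repeats: int = 20,
    master_seed: int = 0,
    n_real: int = 50,
    min_spacing: float | None = None,
) -> pd.DataFrame:
    """Reconstruction error versus the number of measurement points.

    Pattern width fixed at ``sigma_over_R``; ``method`` selects ordinary
    kriging alone ("ok") or the SGS pipeline ("sgs").  For SGS the mean
    node-wise ensemble SD ("spread_mean") tracks realization-to-realization
    variability.
    """
    n_list = np.asarray(sorted(int(n) for n in n_list))
    if np.any(np.diff(n_list) <= 0):
        raise ValidationError("n_list must be strictly increasing")
    if method not in ("ok", "sgs"):
        raise ValidationError(f"unknown method {method!r}")
    R = equivalent_radius(grid)
    if min_spacing is None:
        min_spacing = min(grid.pitch)
    seeds = derive_seeds(master_seed + 1, n_list.size * repeats).reshape(n_list.size, repeats)
    rows = []
    for i, n in enumerate(n_list):
        mae = np.empty(repeats)
        rmse = np.empty(repeats)
        spread = np.full(repeats, np.nan)
        for rep in range(repeats):
            seed = int(seeds[i, rep])
            pattern = gaussian_sampling(
                grid, sigma=sigma_over_R * R, n_points=int(n), seed=seed,
                min_spacing=min_spacing,
            )
            pts = sample_points_from_field(field.values, grid, pattern.positions)
            if method == "ok":
                est = reconstruct_ok(pts, grid)
            else:
                est, ens = reconstruct_sgs(pts, grid, n_real=n_real, master_seed=seed)
                if ens is not None:
                    spread[rep] = float(ens.sd_values.mean())
            m = error_metrics(field.values, est)
            mae[rep], rmse[rep] = m["mae"], m["rmse"]
        rows.append(
            {
                "n_points": int(n), "method": method,
                "mae_mean": mae.mean(), "mae_sd": mae.std(),
                "rmse_mean": rmse.mean(), "rmse_sd": rmse.std(),
                "spread_mean": float(np.nanmean(spread)) if method == "sgs" else np.nan,
                "n_repeats": repeats,
            }
        )
    return pd.DataFrame(rows)
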