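"""Sequential Gaussian simulation (SGS) on a masked intracellular grid.

SGS turns the single "best" kriging surface into an ensemble of equally
plausible surfaces that reproduce both the data and the modeled spatial
variability.  One realization proceeds as follows:

1. values are mapped to standard-normal scores (rank-based normal-score
   transform) and the variogram is fitted on the scores;
2. grid nodes are visited in a uniformly random order;
3. at each node, ordinary kriging from the ``k`` nearest conditioning
   points (measured + previously simulated) yields a conditional mean and
   error variance; a draw from N(mean, variance) is assigned to the node
   and appended to the conditioning set;
4. the finished realization is mapped back to the original units through
   the inverse normal-score transform.

The ensemble mean over many realizations converges to the kriging surface
(in normal-score space) while the per-node spread quantifies local
prediction uncertainty.

The per-node inner loop is JIT-compiled with numba when available; a pure
NumPy implementation of the same algorithm is used as a fallback.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtri
from scipy.stats import rankdata
from skimage.measure import block_reduce

from .exceptions import InsufficientDataError, NumericalError, ValidationError
from .variogram import PointSamples, VariogramModel

__all__ = [
    "NormalScoreMap",
    "SimulationGrid",
    "SgsEnsemble",
    "normal_score",
    "back_transform",
    "build_grid",
    "random_path",
    "sgs_realization",
    "run_ensemble",
]


# --------------------------------------------------------------------------
# normal-score transform
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NormalScoreMap:
    """Monotone table mapping original values <-> standard-normal scores."""

    values: np.ndarray  # ascending, unique
    scores: np.ndarray  # ascending, unique

    def __post_init__(self):
        v, s = np.asarray(self.values, float), np.asarray(self.scores, float)
        if v.shape != s.shape or v.ndim != 1:
            raise ValidationError("malformed normal-score table")
        if not (np.all(np.diff(v) > 0) and np.all(np.diff(s) > 0)):
            raise ValidationError("normal-score table must be strictly increasing")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "scores", s)


def normal_score(values) -> tuple[np.ndarray, NormalScoreMap]:
    """Rank-based normal-score transform.

    Uses the plotting position (k - 0.5)/n mapped through the standard
    normal quantile function; ties receive averaged ranks (and therefore a
    shared score).  Returns the transformed values and the lookup table for
    the inverse transform.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 3:
        raise InsufficientDataError("normal-score transform needs at least 3 values")
    if np.all(values == values[0]):
        raise ValidationError("constant input: normal-score transform degenerate")
    ranks = rankdata(values, method="average")
    scores = ndtri((ranks - 0.5) / n)
    uniq_vals, first = np.unique(values, return_index=True)
    return scores, NormalScoreMap(values=uniq_vals, scores=scores[first])


def back_transform(scores, ns_map: NormalScoreMap, floor: float | None = 0.0) -> np.ndarray:
    """Inverse normal-score transform.

    Linear interpolation inside the table; linear extrapolation beyond the
    table using the slope of the outermost segment; values clamped at
    ``floor`` (default 0, appropriate for diffusion coefficients; pass
    ``None`` to disable).
    """
    s = np.asarray(scores, dtype=float)
    xs, ys = ns_map.scores, ns_map.values
    out = np.interp(s, xs, ys)
    lo_slope = (ys[1] - ys[0]) / (xs[1] - xs[0])
    hi_slope = (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])
    below = s < xs[0]
    above = s > xs[-1]
    out = np.where(below, ys[0] + (s - xs[0]) * lo_slope, out)
    out = np.where(above, ys[-1] + (s - xs[-1]) * hi_slope, out)
    if floor is not None:
        out = np.maximum(out, floor)
    return out


# --------------------------------------------------------------------------
# simulation grid
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationGrid:
    """Masked raster of estimation nodes.

    ``mask`` is the 2-D boolean in-cell indicator at the (possibly
    downsampled) grid resolution; ``nodes`` holds the (x, y) positions (um)
    of the True cells in row-major order; ``pitch`` is the node spacing in
    um (dx, dy).
    """

    shape: tuple
    mask: np.ndarray
    nodes: np.ndarray
    pitch: tuple

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    def to_map(self, node_values, fill=np.nan) -> np.ndarray:
        """Scatter per-node values back onto the 2-D grid (fill elsewhere)."""
        node_values = np.asarray(node_values, dtype=float)
        out = np.full(self.shape, fill, dtype=float)
        out[self.mask] = node_values
        return out

    @classmethod
    def regular(cls, shape, origin=(0.0, 0.0), pitch=(1.0, 1.0)) -> "SimulationGrid":
        """Unmasked rectangular grid (every node retained)."""
        shape = tuple(int(s) for s in shape)
        pitch = (float(np.atleast_1d(pitch)[0]), float(np.atleast_1d(pitch)[-1]))
        mask = np.ones(shape, dtype=bool)
        rr, cc = np.nonzero(mask)
        nodes = np.column_stack(
            [origin[0] + (cc + 0.5) * pitch[0], origin[1] + (rr + 0.5) * pitch[1]]
        )
        return cls(shape=shape, mask=mask, nodes=nodes, pitch=pitch)


def build_grid(cell_mask, pixel_size: float, target_shape=(70, 70)) -> SimulationGrid:
    """Downsample a full-resolution cell mask to a simulation grid.

    The mask is block-averaged down to ``target_shape`` (moving-average
    downsampling); a grid node is retained when at least 50% of its source
    pixels are intracellular.  Masks whose dimensions are not divisible by
    the block size are zero-padded (padding counts as extracellular).
    """
    cell_mask = np.asarray(cell_mask)
    if cell_mask.ndim != 2:
        raise ValidationError("cell mask must be 2-D")
    cell_mask = cell_mask != 0
    if not cell_mask.any():
        raise ValidationError("empty cell mask")
    if pixel_size <= 0:
        raise ValidationError("pixel_size must be positive")
    target_shape = tuple(int(t) for t in target_shape)
    fy = max(int(np.ceil(cell_mask.shape[0] / target_shape[0])), 1)
    fx = max(int(np.ceil(cell_mask.shape[1] / target_shape[1])), 1)
    frac = block_reduce(cell_mask.astype(float), block_size=(fy, fx), func=np.mean)
    frac = frac[: target_shape[0], : target_shape[1]]
    mask = frac >= 0.5
    if not mask.any():
        raise ValidationError("no grid node meets the 50% intracellular rule")
    rr, cc = np.nonzero(mask)
    # node position = center of its source block, in image coordinates
    nodes = np.column_stack(
        [
            (cc * fx + (fx - 1) / 2.0) * pixel_size,
            (rr * fy + (fy - 1) / 2.0) * pixel_size,
        ]
    )
    return SimulationGrid(
        shape=mask.shape, mask=mask, nodes=nodes, pitch=(fx * pixel_size, fy * pixel_size)
    )


def random_path(n_nodes: int, seed) -> np.ndarray:
    """Uniform random visiting order of the grid nodes (a permutation)."""
    if n_nodes < 1:
        raise ValidationError("need at least one node")
    return np.random.default_rng(seed).permutation(n_nodes)


# --------------------------------------------------------------------------
# sequential simulation core
# --------------------------------------------------------------------------

def _sgs_core_py(coords, zvals, n0, nodes, path, a, b, c, k, seed, noise_scale):
    """Sequential simulation inner loop (reference implementation).

    ``coords``/``zvals`` are preallocated to n0 + n_nodes; the first n0
    entries hold the measured data.  Returns node values in path-independent
    (node-index) order.  Conditioning points closer than 1e-9 um to an
    already selected neighbor are skipped so duplicate positions (a node
    coinciding with a datum) cannot make the kriging system singular.
    """
    np.random.seed(seed)
    m = nodes.shape[0]
    out = np.empty(m)
    ncond = n0
    sel = np.empty(k, dtype=np.int64)
    for t in range(m):
        idx = path[t]
        x = nodes[idx, 0]
        y = nodes[idx, 1]
        d2 = (coords[:ncond, 0] - x) ** 2 + (coords[:ncond, 1] - y) ** 2
        order = np.argsort(d2)
        nn = 0
        for oi in range(order.shape[0]):
            cand = order[oi]
            ok = True
            for si in range(nn):
                dx = coords[cand, 0] - coords[sel[si], 0]
                dy = coords[cand, 1] - coords[sel[si], 1]
                if dx * dx + dy * dy < 1e-18:
                    ok = False
                    break
            if ok:
                sel[nn] = cand
                nn += 1
                if nn == k:
                    break
        A = np.ones((nn + 1, nn + 1))
        for i in range(nn):
            A[i, i] = 0.0
            for j in range(i + 1, nn):
                dx = coords[sel[i], 0] - coords[sel[j], 0]
                dy = coords[sel[i], 1] - coords[sel[j], 1]
                h = np.sqrt(dx * dx + dy * dy)
                if h > 0.0:
                    g = b + (c - b) * (1.0 - np.exp(-h / a))
                else:
                    g = 0.0
                A[i, j] = g
                A[j, i] = g
        A[nn, nn] = 0.0
        # rhs uses the continuous h -> 0+ limit (gamma -> b at zero distance):
        # a positive nugget then filters noise at data-coincident nodes,
        # while b = 0 keeps kriging exact there
        rhs = np.ones(nn + 1)
        for i in range(nn):
            h = np.sqrt(d2[sel[i]])
            rhs[i] = b + (c - b) * (1.0 - np.exp(-h / a))
        sol = np.linalg.solve(A, rhs)
        est = 0.0
        var = sol[nn]
        for i in range(nn):
            est += sol[i] * zvals[sel[i]]
            var += sol[i] * rhs[i]
        if var < 0.0:
            var = 0.0
        val = est + np.random.normal() * np.sqrt(var) * noise_scale
        out[idx] = val
        coords[ncond, 0] = x
        coords[ncond, 1] = y
        zvals[ncond] = val
        ncond += 1
    return out


try:  # compile the inner loop; fall back to pure NumPy on any failure
    import numba

    _sgs_core = numba.njit(_sgs_core_py, cache=False, fastmath=False)
    _sgs_core(
        np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 0.0], [0.0, 0.0]]),
        np.array([0.0, 1.0, 0.0, 0.0]),
        2,
        np.array([[0.5, 0.5], [0.2, 0.8]]),
        np.array([0, 1], dtype=np.int64),
        1.0, 0.0, 1.0, 8, 1, 1.0,
    )
except Exception:  # pragma: no cover - exercised only without a working numba
    _sgs_core = _sgs_core_py


def sgs_realization(
    points: PointSamples,
    model: VariogramModel,
    grid: SimulationGrid,
    seed: int,
    noise_scale: float = 1.0,
    k_neighbors: int = 24,
) -> np.ndarray:
    """One conditional realization on the grid, in the data's (normal) space.

    ``points`` are expected to be normal-score transformed and ``model``
    fitted on the scores; the caller applies the back-transform.  With
    ``noise_scale = 0`` the realization degenerates to the sequential
    kriging-only surface.  The visiting order and the Gaussian draws both
    derive from ``seed``.
    """
    if grid.n_nodes < 1:
        raise ValidationError("empty simulation grid")
    if model.c <= 0:
        raise NumericalError(
            "degenerate variogram (sill = 0): conditional simulation undefined"
        )
    n0 = len(points)
    m = grid.n_nodes
    seed = int(seed) % (2**31 - 1)
    path = random_path(m, seed)
    coords = np.zeros((n0 + m, 2))
    coords[:n0] = points.u
    zvals = np.zeros(n0 + m)
    zvals[:n0] = points.z
    k = int(min(k_neighbors, n0 + m))
    return _sgs_core(
        coords, zvals, n0, grid.nodes, path.astype(np.int64),
        float(model.a), float(model.b), float(model.c),
        k, seed, float(noise_scale),
    )


@dataclass(frozen=True)
class SgsEnsemble:
    """A stack of SGS realizations with its node-wise summary statistics."""

    realizations: np.ndarray  # (n_real, n_nodes)
    mean_values: np.ndarray
    sd_values: np.ndarray
    grid: SimulationGrid
    master_seed: int
    realization_seeds: np.ndarray

    @property
    def n_real(self) -> int:
        return self.realizations.shape[0]

    @property
    def mean_map(self) -> np.ndarray:
        return self.grid.to_map(self.mean_values)

    @property
    def sd_map(self) -> np.ndarray:
        return self.grid.to_map(self.sd_values)


def running_mean_stabilization(
    points: PointSamples,
    model: VariogramModel,
    grid: SimulationGrid,
    master_seed: int = 0,
    normal_score_map: NormalScoreMap | None = None,
    value_floor: float | None = 0.0,
    batch: int = 10,
    rel_tol: float = 0.02,
    max_real: int = 200,
    k_neighbors: int = 24,
) -> tuple[int, bool]:
    """How many realizations until the ensemble mean stabilizes?

    Realizations are added one at a time; after every ``batch`` of them the
    running mean map is compared with the previous checkpoint.  The
    ensemble is declared stable at the first count where the maximum
    per-node relative change falls below ``rel_tol``.  Returns
    ``(count, stabilized)``; ``count`` is ``max_real`` when the criterion
    is never met.
    """
    seeds = derive_seeds(master_seed, max_real)
    total = np.zeros(grid.n_nodes)
    prev_mean = None
    for r in range(max_real):
        vals = sgs_realization(
            points, model, grid, seed=int(seeds[r]),
            k_neighbors=k_neighbors,
        )
        if normal_score_map is not None:
            vals = back_transform(vals, normal_score_map, floor=value_floor)
        total += vals
        n = r + 1
        if n % batch == 0:
            mean = total / n
            if prev_mean is not None:
                denom = np.maximum(np.abs(prev_mean), 1e-300)
                if float(np.max(np.abs(mean - prev_mean) / denom)) < rel_tol:
                    return n, True
            prev_mean = mean
    return max_real, False


def derive_seeds(master_seed: int, n: int) -> np.ndarray:
    """Per-realization seeds: SeedSequence stream reduced below 2^31."""
    ss = np.random.SeedSequence(int(master_seed))
    return (ss.generate_state(n, dtype=np.uint64) % (2**31 - 1)).astype(np.int64)


def run_ensemble(
    points: PointSamples,
    model: VariogramModel,
    grid: SimulationGrid,
    n_real: int = 100,
    master_seed: int = 0,
    noise_scale: float = 1.0,
    k_neighbors: int = 24,
    normal_score_map: NormalScoreMap | None = None,
    value_floor: float | None = 0.0,
) -> SgsEnsemble:
    """Run ``n_real`` independent realizations and aggregate them.

    Each realization uses a fresh random path and fresh Gaussian draws
    (seed derived from ``master_seed``).  When ``normal_score_map`` is
    given, every realization is back-transformed to original units before
    the mean and per-node standard deviation are computed, so the summary
    maps live in original units.
    """
    if n_real < 1:
        raise ValidationError("need at least one realization")
    seeds = derive_seeds(master_seed, n_real)
    reals = np.empty((n_real, grid.n_nodes))
    for r in range(n_real):
        vals = sgs_realization(
            points, model, grid, seed=int(seeds[r]),
            noise_scale=noise_scale, k_neighbors=k_neighbors,
        )
        if normal_score_map is not None:
            vals = back_transform(vals, normal_score_map, floor=value_floor)
        reals[r] = vals
    return SgsEnsemble(
        realizations=reals,
        mean_values=reals.mean(axis=0),
        sd_values=reals.std(axis=0),
        grid=grid,
        master_seed=int(master_seed),
        realization_seeds=seeds,
    )
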