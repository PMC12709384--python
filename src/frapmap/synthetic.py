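"""Synthetic data generators with known ground truth.

Every stage of the mapping pipeline can be exercised without experimental
data: FRAP stacks are forward-modeled from the Gaussian recovery profile,
spatially correlated diffusivity fields are drawn as Gaussian random fields
with an exponential variogram, and FCS autocorrelation curves come from the
two-component diffusion model.  All generators are bit-reproducible given a
seed.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .exceptions import NumericalError, ValidationError
from .frap import FrapStack, recovery_model
from .fcs import AcfCurve, dual_component_model
from .sgs import SimulationGrid
from .variogram import PointSamples, VariogramModel

__all__ = [
    "simulate_frap_stack",
    "simulate_grf",
    "sample_points_from_field",
    "simulate_acf",
]


def simulate_frap_stack(
    D: float,
    A1: float,
    A2: float,
    rho: float,
    spots,
    shape=(64, 64),
    pixel_size: float = 0.2,
    frame_interval: float = 0.2,
    n_prebleach: int = 2,
    n_recovery: int = 15,
    noise_sd: float = 0.0,
    decay_rate: float = 0.0,
    seed: int | None = None,
) -> FrapStack:
    """Forward-model a FRAP stack from the Gaussian recovery profile.

    ``D`` may be a scalar (shared by all spots) or a sequence with one value
    per spot.  Frames: ``n_prebleach`` uniform pre-bleach frames at A1, one
    bleach frame, then ``n_recovery`` recovery frames evaluated at
    t = (j + 1/2) * frame_interval for recovery frame j.  Optional global
    exponential decay exp(-decay_rate * frame_index) and additive Gaussian
    noise (clipped at 0 to keep intensities physical).
    """
    spots = list(spots)
    if not spots:
        raise ValidationError("need at least one bleach spot")
    Ds = np.broadcast_to(np.asarray(D, dtype=float), (len(spots),))
    nrow, ncol = shape
    xmax, ymax = (ncol - 1) * pixel_size, (nrow - 1) * pixel_size
    for spot in spots:
        x, y = spot.center
        if not (0 <= x <= xmax and 0 <= y <= ymax):
            raise ValidationError(f"spot center {spot.center} outside image")
    x = np.arange(ncol) * pixel_size
    y = np.arange(nrow) * pixel_size
    X, Y = np.meshgrid(x, y)

    bleach_end = n_prebleach + 1
    n_frames = bleach_end + n_recovery
    frames = np.full((n_frames, nrow, ncol), float(A1))
    # bleach frame and recovery frames carry the spot signatures
    for j in range(n_prebleach, n_frames):
        if j < bleach_end:
            t = 1e-3  # bleach frame: essentially the initial profile
        else:
            t = (j - bleach_end + 0.5) * frame_interval
        frame = np.full((nrow, ncol), float(A1))
        for spot, Dk in zip(spots, Ds):
            r = np.hypot(X - spot.center[0], Y - spot.center[1])
            frame += recovery_model(r, t, Dk, 0.0, A2, rho)
        frames[j] = frame
    if decay_rate > 0:
        frames *= np.exp(-decay_rate * np.arange(n_frames))[:, None, None]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        frames = np.maximum(frames + rng.normal(0.0, noise_sd, frames.shape), 0.0)
    return FrapStack(
        frames=frames,
        pixel_size=pixel_size,
        frame_interval=frame_interval,
        n_prebleach=n_prebleach,
        bleach_end_index=bleach_end,
    )


def simulate_grf(
    grid: SimulationGrid,
    model: VariogramModel,
    mean: float = 0.0,
    seed: int | None = None,
    max_nodes: int = 5000,
) -> np.ndarray:
    """Draw a Gaussian random field on the grid nodes by dense factorization.

    The covariance corresponding to the exponential variogram is
    C(h) = (c - b) exp(-h / a) for h > 0 with C(0) = c: the nugget b is
    realized as i.i.d. node noise.  Cholesky with a jitter-and-retry ladder;
    node count limited to ``max_nodes``.
    """
    nodes = grid.nodes
    m = nodes.shape[0]
    if m > max_nodes:
        raise ValidationError(f"grid too large for dense simulation ({m} > {max_nodes})")
    rng = np.random.default_rng(seed)
    if model.c == 0:
        return np.full(m, float(mean))
    C = (model.c - model.b) * np.exp(-squareform(pdist(nodes)) / model.a)
    np.fill_diagonal(C, model.c)
    jitter = 0.0
    for _ in range(6):
        try:
            L = np.linalg.cholesky(C + jitter * np.eye(m))
            break
        except np.linalg.LinAlgError:
            jitter = max(jitter * 10.0, 1e-12 * model.c)
    else:
        raise NumericalError("covariance matrix not positive definite after jitter")
    return mean + L @ rng.standard_normal(m)


def sample_points_from_field(
    field_values,
    grid: SimulationGrid,
    positions,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> PointSamples:
    """Read the field at the node nearest each position, plus optional noise.

    Positions must fall within half a grid pitch of a masked-in node.
    """
    field_values = np.asarray(field_values, dtype=float)
    positions = np.asarray(positions, dtype=float).reshape(-1, 2)
    if field_values.shape != (grid.n_nodes,):
        raise ValidationError("field must have one value per grid node")
    half_diag = 0.5 * float(np.hypot(*grid.pitch))
    d = np.linalg.norm(grid.nodes[None, :, :] - positions[:, None, :], axis=2)
    nearest = d.argmin(axis=1)
    if np.any(d[np.arange(len(positions)), nearest] > half_diag + 1e-9):
        raise ValidationError("a sampling position lies outside the masked grid")
    z = field_values[nearest]
    if noise_sd > 0:
        z = z + np.random.default_rng(seed).normal(0.0, noise_sd, z.size)
    return PointSamples(u=positions, z=z)


def simulate_acf(
    N1: float,
    N2: float,
    tauD1: float,
    tauD2: float,
    S: float = 2.67,
    lags=None,
    noise_frac: float = 0.0,
    seed: int | None = None,
) -> AcfCurve:
    """Generate a two-component model ACF, optionally with multiplicative noise."""
    if lags is None:
        lags = np.geomspace(1e-6, 1.0, 80)
    lags = np.asarray(lags, dtype=float)
    G = dual_component_model(lags, N1, N2, tauD1, tauD2, S)
    if noise_frac > 0:
        rng = np.random.default_rng(seed)
        G = G * (1.0 + rng.normal(0.0, noise_frac, G.size))
    return AcfCurve(tau=lags, G=G)
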