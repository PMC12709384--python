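"""Empirical semivariograms and the exponential variogram model.

The semivariogram quantifies how the half mean-squared difference between
measurements grows with their separation distance h.  For every unordered
pair of points (i, j) the raw ("cloud") semivariance is

    gamma_ij = 0.5 * (Z_i - Z_j)**2      at lag  h_ij = |u_i - u_j|.

Spatial structure is summarized by fitting an exponential model

    gamma(h) = b + (c - b) * (1 - exp(-h / a))   for h > 0,   gamma(0) = 0,

with correlation length (range) ``a``, nugget ``b`` and sill ``c``.  The
model is fitted to the full variogram cloud by bounded nonlinear least
squares; binned fitting is exposed as an option for plotting and robustness
experiments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.distance import pdist

from .exceptions import InsufficientDataError, ValidationError

__all__ = [
    "PointSamples",
    "VariogramCloud",
    "VariogramModel",
    "semivariogram_cloud",
    "bin_cloud",
    "fit_exponential",
    "model_gamma",
]


@dataclass(frozen=True)
class PointSamples:
    """Sparse point measurements: positions ``u`` (n, 2) in um and values ``z``.

    For diffusion mapping ``z`` holds diffusion coefficients in um^2/s, but
    the geostatistical machinery is unit-agnostic.
    """

    u: np.ndarray
    z: np.ndarray

    def __post_init__(self):
        u = np.asarray(self.u, dtype=float)
        z = np.asarray(self.z, dtype=float)
        if u.ndim != 2 or u.shape[1] != 2:
            raise ValidationError("positions must be an (n, 2) array")
        if z.shape != (u.shape[0],):
            raise ValidationError("values must be a length-n vector")
        if not (np.all(np.isfinite(u)) and np.all(np.isfinite(z))):
            raise ValidationError("positions and values must be finite")
        object.__setattr__(self, "u", u)
        object.__setattr__(self, "z", z)

    def __len__(self) -> int:
        return self.u.shape[0]


@dataclass(frozen=True)
class VariogramCloud:
    """All unordered pairwise (lag, semivariance) pairs of a dataset."""

    h: np.ndarray
    gamma: np.ndarray

    def __post_init__(self):
        h = np.asarray(self.h, dtype=float)
        g = np.asarray(self.gamma, dtype=float)
        if h.shape != g.shape or h.ndim != 1:
            raise ValidationError("lags and semivariances must be equal-length vectors")
        object.__setattr__(self, "h", h)
        object.__setattr__(self, "gamma", g)

    def __len__(self) -> int:
        return self.h.size


@dataclass(frozen=True)
class VariogramModel:
    """Exponential variogram: range ``a`` (um), nugget ``b``, sill ``c``."""

    a: float
    b: float
    c: float

    def __post_init__(self):
        if not self.a > 0:
            raise ValidationError("range a must be > 0")
        if not (0 <= self.b <= self.c):
            raise ValidationError("need 0 <= nugget b <= sill c")

    def __call__(self, h):
        return model_gamma(self, h)


def semivariogram_cloud(points: PointSamples) -> VariogramCloud:
    """Compute the variogram cloud: one (h, gamma) pair per unordered point pair.

    Pairs at identical positions (h = 0) are retained; they carry nugget
    information when the values differ.
    """
    n = len(points)
    if n < 2:
        raise InsufficientDataError("need at least 2 points for a variogram cloud")
    h = pdist(points.u)
    gamma = 0.5 * pdist(points.z[:, None], metric="sqeuclidean")
    return VariogramCloud(h=h, gamma=gamma)


def bin_cloud(cloud: VariogramCloud, n_bins: int = 12, max_lag: float | None = None):
    """Average the cloud into equal-width lag bins.

    Returns ``(h_mid, gamma_mean, counts)`` with empty bins omitted.  The
    default ``max_lag`` is the maximum pairwise distance in the cloud.
    """
    if len(cloud) == 0:
        raise InsufficientDataError("empty variogram cloud")
    if max_lag is None:
        max_lag = float(cloud.h.max())
    if max_lag <= 0:
        raise ValidationError("max_lag must be positive")
    edges = np.linspace(0.0, max_lag, n_bins + 1)
    # right edge inclusive so the max-lag pair lands in the last bin
    idx = np.clip(np.digitize(cloud.h, edges[1:], right=True), 0, n_bins - 1)
    keep = cloud.h <= max_lag
    counts = np.bincount(idx[keep], minlength=n_bins)
    sums = np.bincount(idx[keep], weights=cloud.gamma[keep], minlength=n_bins)
    nonempty = counts > 0
    h_mid = 0.5 * (edges[:-1] + edges[1:])
    return h_mid[nonempty], sums[nonempty] / counts[nonempty], counts[nonempty]


def model_gamma(model: VariogramModel, h):
    """Evaluate the exponential variogram, with gamma(0) = 0 exactly.

    The nugget produces a discontinuity at the origin: gamma -> b as
    h -> 0+ but gamma(0) = 0.
    """
    h = np.asarray(h, dtype=float)
    if np.any(h < 0):
        raise ValidationError("lag distances must be non-negative")
    out = model.b + (model.c - model.b) * (1.0 - np.exp(-h / model.a))
    out = np.where(h > 0, out, 0.0)
    if out.ndim == 0:
        return float(out)
    return out


def fit_exponential(
    cloud: VariogramCloud,
    bounds: dict | None = None,
    weights: np.ndarray | None = None,
) -> VariogramModel:
    """Fit the exponential model to a variogram cloud by least squares.

    Only pairs with h > 0 enter the objective (gamma(0) is identically 0 by
    definition and carries no information about a, b, c).  Constraints
    a > 0 and 0 <= b <= c are enforced through a reparametrization
    c = b + spread, spread >= 0.

    A completely flat cloud (all semivariances equal) is degenerate: the fit
    returns b = c = mean gamma with a = max lag and a warning.

    For parameter-recovery work on noisy data, prefer fitting binned values
    with ``weights`` set to the per-bin pair counts (see
    :func:`fit_exponential_binned`): individual cloud semivariances are
    chi-square distributed with one degree of freedom, and the raw-cloud
    least-squares estimate of the range is heavy-tailed as a result.

    Parameters
    ----------
    cloud : VariogramCloud
        Raw pairs, or pre-binned values packed into a cloud.
    bounds : dict, optional
        Optional ``{"a": (lo, hi), "b": (lo, hi), "c": (lo, hi)}`` overrides.
    weights : array, optional
        Per-pair weights (e.g. bin counts when fitting binned values).
    """
    pos = cloud.h > 0
    h = cloud.h[pos]
    g = cloud.gamma[pos]
    w = None if weights is None else np.sqrt(np.asarray(weights, dtype=float)[pos])
    if np.unique(h).size < 3:
        raise InsufficientDataError("need at least 3 distinct positive lags")
    if np.allclose(g, g[0]):
        level = float(np.mean(g))
        warnings.warn(
            "flat variogram cloud: no resolvable spatial structure; "
            "returning nugget = sill = mean semivariance",
            stacklevel=2,
        )
        if level == 0.0:
            return VariogramModel(a=float(h.max()), b=0.0, c=0.0)
        return VariogramModel(a=float(h.max()), b=level, c=level)

    hmax = float(h.max())
    # ranges beyond the largest observed lag are not resolvable from the
    # data, so a is bounded by it unless the caller overrides
    b_lo, b_hi = (0.0, np.inf) if bounds is None else bounds.get("b", (0.0, np.inf))
    a_lo, a_hi = (1e-9, hmax) if bounds is None else bounds.get("a", (1e-9, hmax))

    def resid(theta):
        a, b, spread = theta
        r = (b + spread * (1.0 - np.exp(-h / a))) - g
        return r if w is None else w * r

    a0 = hmax / 3.0
    b0 = max(float(np.min(bin_cloud(cloud)[1])), 0.0)
    c0 = max(float(np.mean(g)), b0 + 1e-12)
    sol = least_squares(
        resid,
        x0=[a0, b0, max(c0 - b0, 1e-12)],
        bounds=([a_lo, b_lo, 0.0], [a_hi, b_hi, np.inf]),
        method="trf",
    )
    a, b, spread = sol.x
    return VariogramModel(a=float(a), b=float(b), c=float(b + spread))


def fit_exponential_binned(
    cloud: VariogramCloud, n_bins: int = 20, max_lag_frac: float = 0.5
) -> VariogramModel:
    """Exponential fit on the count-weighted binned semivariogram.

    Bins span ``max_lag_frac`` of the maximum pairwise lag (half by
    default: beyond that, few pairs per lag and edge effects dominate) and
    each bin mean is weighted by its pair count.  More stable than the
    raw-cloud fit for parameter recovery.
    """
    h, g, counts = bin_cloud(cloud, n_bins=n_bins,
                             max_lag=max_lag_frac * float(cloud.h.max()))
    return fit_exponential(
        VariogramCloud(h=h, gamma=g),
        weights=counts,
        bounds={"a": (1e-9, float(cloud.h.max()))},
    )
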