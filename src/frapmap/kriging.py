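"""Ordinary kriging: best linear unbiased prediction from a variogram.

The estimate at an unobserved location u_o is Z*(u_o) = sum_k w_k Z(u_k)
with weights solving the semivariogram-form system

    sum_k w_k gamma(h_jk) + mu = gamma(h_jo),  j = 1..n
    sum_k w_k = 1

where mu is the Lagrange multiplier enforcing unbiasedness.  The minimized
prediction variance is sigma^2 = sum_k w_k gamma(h_ko) + mu.

With a zero nugget, kriging is an exact interpolator: predicting at a data
location reproduces the datum with zero variance.  A positive nugget
filters measurement noise and the surface no longer honors the data
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import lu_factor, lu_solve
from scipy.spatial.distance import cdist, squareform, pdist

from .exceptions import InsufficientDataError, NumericalError, ValidationError
from .variogram import PointSamples, VariogramModel, model_gamma

__all__ = [
    "KrigingResult",
    "CvReport",
    "krige_point",
    "krige_map",
    "loo_cross_validate",
    "summarize_cv",
    "dedupe_points",
]


@dataclass(frozen=True)
class KrigingResult:
    """Ordinary-kriging prediction at one location."""

    estimate: float
    error_variance: float
    weights: np.ndarray
    lagrange: float


@dataclass(frozen=True)
class CvReport:
    """Leave-one-out cross-validation summary.

    ``accuracy_percent`` is 100 * (1 - mean_k |pred_k - obs_k| / |obs_k|)
    floored at 0; points with obs = 0 are excluded (relative error
    undefined).  MAE and RMSE are reported alongside so any other summary
    can be derived from the per-point pairs.
    """

    observed: np.ndarray
    predicted: np.ndarray
    accuracy_percent: float
    mae: float
    rmse: float
    method: str
    n_excluded: int = 0


def dedupe_points(points: PointSamples, tol: float = 1e-9) -> PointSamples:
    """Average values at coincident positions so kriging systems stay nonsingular."""
    u = points.u
    # group by rounded coordinates
    key = np.round(u / max(tol, 1e-12)).astype(np.int64)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    if np.all(counts == 1):
        return points
    m = counts.size
    u_new = np.zeros((m, 2))
    z_new = np.zeros(m)
    np.add.at(u_new, inv, u)
    np.add.at(z_new, inv, points.z)
    return PointSamples(u=u_new / counts[:, None], z=z_new / counts)


def _gamma_rhs(model: VariogramModel, h):
    """Variogram for the right-hand side: the continuous (h -> 0+) limit.

    Using gamma -> b instead of the literal gamma(0) = 0 at zero distance
    treats a prediction point collocated with a datum as a distinct
    location, so a positive nugget filters measurement noise rather than
    reproducing it; with b = 0 the two conventions coincide and kriging is
    an exact interpolator.
    """
    h = np.asarray(h, dtype=float)
    out = model.b + (model.c - model.b) * (1.0 - np.exp(-h / model.a))
    if out.ndim == 0:
        return float(out)
    return out


def _build_system(points: PointSamples, model: VariogramModel):
    n = len(points)
    A = np.ones((n + 1, n + 1))
    if n > 1:
        A[:n, :n] = squareform(model_gamma(model, pdist(points.u)))
    else:
        A[:n, :n] = 0.0
    np.fill_diagonal(A[:n, :n], 0.0)
    A[n, n] = 0.0
    return A


def _solve(A, rhs, context: str = "kriging system"):
    try:
        lu = lu_factor(A)
    except Exception as exc:  # pragma: no cover - scipy raises rarely here
        raise NumericalError(f"failed to factorize {context}: {exc}") from exc
    sol = lu_solve(lu, rhs)
    if not np.all(np.isfinite(sol)):
        raise NumericalError(
            f"singular {context} (check for coincident points or a degenerate "
            "variogram with zero sill)"
        )
    # cheap singularity guard: residual check
    if not np.allclose(A @ sol, rhs, atol=1e-8 * max(1.0, np.abs(rhs).max())):
        raise NumericalError(f"ill-conditioned {context}: solve residual too large")
    return sol


def krige_point(
    points: PointSamples, model: VariogramModel, u_o, *, deduped: bool = False
) -> KrigingResult:
    """Ordinary-kriging prediction at a single location ``u_o``.

    Coincident conditioning points are averaged first (disable with
    ``deduped=True`` when the caller guarantees distinct positions).
    """
    if len(points) < 1:
        raise InsufficientDataError("kriging needs at least one conditioning point")
    if not deduped:
        points = dedupe_points(points)
    n = len(points)
    u_o = np.asarray(u_o, dtype=float).reshape(2)
    if n == 1:
        return _krige_single(points, model, u_o)
    return _krige_general(points, model, u_o)


def _krige_single(points: PointSamples, model: VariogramModel, u_o) -> KrigingResult:
    # n = 1: system [[0,1],[1,0]] [w, mu] = [g, 1] -> w = 1, mu = g
    g = float(_gamma_rhs(model, float(np.linalg.norm(points.u[0] - u_o))))
    return KrigingResult(
        estimate=float(points.z[0]),
        error_variance=max(g + g, 0.0),
        weights=np.array([1.0]),
        lagrange=g,
    )


def _krige_general(points: PointSamples, model: VariogramModel, u_o) -> KrigingResult:
    n = len(points)
    A = _build_system(points, model)
    rhs = np.empty(n + 1)
    rhs[:n] = _gamma_rhs(model, np.linalg.norm(points.u - u_o, axis=1))
    rhs[n] = 1.0
    sol = _solve(A, rhs)
    w, mu = sol[:n], float(sol[n])
    var = float(w @ rhs[:n] + mu)
    return KrigingResult(
        estimate=float(w @ points.z),
        error_variance=max(var, 0.0),
        weights=w,
        lagrange=mu,
    )


def krige_map(points: PointSamples, model: VariogramModel, grid):
    """Kriging over all nodes of a :class:`~frapmap.sgs.SimulationGrid`.

    The (n+1) system matrix is factorized once and reused for every node.
    Returns 2-D estimate and error-variance maps with NaN outside the mask.
    """
    points = dedupe_points(points)
    n = len(points)
    nodes = grid.nodes
    if nodes.shape[0] == 0:
        raise ValidationError("empty simulation grid")
    est = np.full(grid.shape, np.nan, dtype=float)
    var = np.full(grid.shape, np.nan, dtype=float)
    if n == 1:
        g = _gamma_rhs(model, np.linalg.norm(nodes - points.u[0], axis=1))
        est[grid.mask] = points.z[0]
        var[grid.mask] = np.maximum(2.0 * g, 0.0)
        return est, var
    A = _build_system(points, model)
    lu = lu_factor(A)
    rhs = np.ones((n + 1, nodes.shape[0]))
    rhs[:n, :] = _gamma_rhs(model, cdist(points.u, nodes))
    sol = lu_solve(lu, rhs)
    if not np.all(np.isfinite(sol)):
        raise NumericalError("singular kriging system over grid")
    w, mu = sol[:n, :], sol[n, :]
    est[grid.mask] = points.z @ w
    var[grid.mask] = np.maximum(np.sum(w * rhs[:n, :], axis=0) + mu, 0.0)
    return est, var


def loo_cross_validate(
    points: PointSamples,
    model: VariogramModel,
    predictor: str = "ok",
    *,
    refit_variogram: bool = False,
    seed: int | None = None,
    sgs_options: dict | None = None,
) -> CvReport:
    """Leave-one-out cross-validation of spatial prediction.

    Each point is predicted from the remaining n-1 points.  Predictors:

    - ``"ok"``: ordinary kriging with the supplied variogram model
      (optionally refitted per fold on the training points).
    - ``"sgs_mean"``: the full normal-score SGS ensemble mean evaluated at
      the held-out location (the stochastic-simulation analogue of the
      kriging estimate; see :mod:`frapmap.sgs`).

    Accuracy = 100 * (1 - mean relative absolute error), floored at 0.
    """
    n = len(points)
    if n < 4:
        raise InsufficientDataError("LOO cross-validation needs at least 4 points")
    if predictor not in ("ok", "sgs_mean"):
        raise ValidationError(f"unknown predictor {predictor!r}")

    ns_map = ns_model = scores_all = None
    if predictor == "sgs_mean":
        from .sgs import normal_score
        from .variogram import fit_exponential, semivariogram_cloud

        # mirror the mapping pipeline: transform and score-space variogram
        # fitted once on the full dataset (per-fold refit only on request)
        scores_all, ns_map = normal_score(points.z)
        if not refit_variogram:
            ns_model = fit_exponential(
                semivariogram_cloud(PointSamples(u=points.u, z=scores_all))
            )

    preds = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        train = PointSamples(u=points.u[keep], z=points.z[keep])
        fold_model = model
        if refit_variogram:
            from .variogram import fit_exponential, semivariogram_cloud

            fold_model = fit_exponential(semivariogram_cloud(train))
        if predictor == "ok":
            preds[i] = krige_point(train, fold_model, points.u[i]).estimate
        else:
            fold_ns_model = ns_model
            if refit_variogram:
                from .variogram import fit_exponential, semivariogram_cloud

                fold_ns_model = fit_exponential(
                    semivariogram_cloud(PointSamples(u=train.u, z=scores_all[keep]))
                )
            preds[i] = _sgs_mean_at(
                PointSamples(u=train.u, z=scores_all[keep]),
                points.u[i],
                ns_map,
                fold_ns_model,
                seed=(seed or 0) + i,
                options=sgs_options or {},
            )

    return summarize_cv(points.z, preds, method="ok" if predictor == "ok" else "sgs")


def summarize_cv(observed, predicted, method: str = "ok") -> CvReport:
    """Fold per-point (observed, predicted) pairs into a CvReport.

    Accuracy = 100 * (1 - mean_k |pred_k - obs_k| / |obs_k|), floored at 0;
    observations equal to 0 are excluded from the relative-error mean (with
    a warning) but still enter MAE and RMSE.
    """
    import warnings

    obs = np.asarray(observed, dtype=float)
    preds = np.asarray(predicted, dtype=float)
    if obs.shape != preds.shape:
        raise ValidationError("observed and predicted lengths differ")
    nonzero = obs != 0
    n_excluded = int(np.sum(~nonzero))
    if n_excluded:
        warnings.warn(
            f"{n_excluded} observation(s) equal to 0 excluded from relative accuracy",
            stacklevel=2,
        )
    rel = np.abs(preds[nonzero] - obs[nonzero]) / np.abs(obs[nonzero])
    accuracy = max(100.0 * (1.0 - float(np.mean(rel))), 0.0)
    err = preds - obs
    return CvReport(
        observed=obs.copy(),
        predicted=preds,
        accuracy_percent=accuracy,
        mae=float(np.mean(np.abs(err))),
        rmse=float(np.sqrt(np.mean(err**2))),
        method=method,
        n_excluded=n_excluded,
    )


def _sgs_mean_at(
    ns_train: PointSamples, u_target, ns_map, ns_model, seed: int, options: dict
) -> float:
    """SGS-ensemble-mean prediction at one location.

    ``ns_train`` holds the training points already in normal-score space,
    with ``ns_map`` the (full-data) transform table and ``ns_model`` the
    score-space variogram.  Runs the SGS ensemble on a small grid spanning
    the training points, translated so one node coincides exactly with the
    target (no nearest-node discretization error), and returns the ensemble
    mean there in original units.  Grid geometry and realization count come
    from ``options`` (``grid_shape``, ``n_real``, ``k_neighbors``).
    """
    from .sgs import SimulationGrid, run_ensemble

    shape = options.get("grid_shape", (13, 13))
    n_real = options.get("n_real", 100)
    k = options.get("k_neighbors", 24)

    u_target = np.asarray(u_target, dtype=float).reshape(2)
    pts_all = np.vstack([ns_train.u, u_target[None, :]])
    lo = pts_all.min(axis=0) - 1.0
    hi = pts_all.max(axis=0) + 1.0
    pitch = (hi - lo) / np.array(shape[::-1])  # (dx, dy)
    grid = SimulationGrid.regular(shape=shape, origin=lo, pitch=pitch)
    node = int(np.argmin(np.linalg.norm(grid.nodes - u_target, axis=1)))
    shift = u_target - grid.nodes[node]
    grid = SimulationGrid(
        shape=grid.shape, mask=grid.mask, nodes=grid.nodes + shift, pitch=grid.pitch
    )

    ens = run_ensemble(
        ns_train,
        ns_model,
        grid,
        n_real=n_real,
        master_seed=seed,
        k_neighbors=k,
        normal_score_map=ns_map,
        value_floor=None,
    )
    return float(ens.mean_values[node])
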