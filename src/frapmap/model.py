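"""Whole-cell diffusion mapping as a fitted spatial model.

:class:`DiffusionMap` bundles the sparse FRAP-derived point measurements
with the cell geometry; :meth:`DiffusionMap.fit` runs the full mapping
pipeline —

1. Moran's I test for spatial autocorrelation (the method's premise);
2. normal-score transform of the diffusion coefficients;
3. exponential-variogram fit on the scores;
4. conditional sequential Gaussian simulation ensemble on the masked grid;
5. back-transform and aggregation into mean and spread maps;
6. leave-one-out cross-validation of the spatial predictor —

and returns a :class:`DiffusionMapResults` carrying the maps, the fitted
spatial-structure parameters, diagnostics, and a ``summary()`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .autocorr import SIGNIFICANCE_ALPHA, MoranResult, moran_test
from .exceptions import ValidationError
from .kriging import CvReport, dedupe_points, krige_map, loo_cross_validate
from .sgs import (
    NormalScoreMap,
    SgsEnsemble,
    SimulationGrid,
    build_grid,
    normal_score,
    run_ensemble,
)
from .variogram import PointSamples, VariogramModel, fit_exponential, semivariogram_cloud

__all__ = ["DiffusionMap", "DiffusionMapResults"]


class DiffusionMap:
    """Spatial model for mapping sparse diffusion measurements over a cell.

    Parameters
    ----------
    points : PointSamples
        Measurement positions (um) and diffusion coefficients (um^2/s).
    cell_mask : 2-D array, optional
        Full-resolution binary mask (nonzero = intracellular); downsampled
        onto ``grid_shape`` simulation nodes.  Alternatively pass a
        pre-built ``grid``.
    pixel_size : float
        Mask pixel size in um (required with ``cell_mask``).
    grid_shape : tuple
        Simulation grid shape after moving-average downsampling.
    """

    def __init__(
        self,
        points: PointSamples,
        cell_mask=None,
        pixel_size: float | None = None,
        grid_shape=(70, 70),
        grid: SimulationGrid | None = None,
    ):
        if grid is None:
            if cell_mask is None or pixel_size is None:
                raise ValidationError("provide either a grid or cell_mask + pixel_size")
            grid = build_grid(cell_mask, pixel_size, target_shape=grid_shape)
        self.points = dedupe_points(points)
        self.grid = grid
        if len(self.points) < 10:
            warnings.warn(
                f"only {len(self.points)} measurement points: spatial-structure "
                "estimates will be unstable (>= 10 recommended)",
                stacklevel=2,
            )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "DiffusionMap":
        """Build from a table with columns x_um, y_um, D_um2_s."""
        missing = {"x_um", "y_um", "D_um2_s"} - set(df.columns)
        if missing:
            raise ValidationError(f"point table missing column(s): {sorted(missing)}")
        pts = PointSamples(
            u=df[["x_um", "y_um"]].to_numpy(float), z=df["D_um2_s"].to_numpy(float)
        )
        return cls(pts, **kwargs)

    def fit(
        self,
        n_realizations: int = 100,
        seed: int = 0,
        k_neighbors: int = 24,
        cv: str | None = "ok",
        moran_mode: str = "analytic",
        fit_variogram_on: str = "scores",
    ) -> "DiffusionMapResults":
        """Run the mapping pipeline and return results.

        ``cv`` selects the cross-validation predictor ("ok", "sgs_mean" or
        None to skip).  ``fit_variogram_on`` chooses whether the variogram
        is fitted on normal scores (default, standard simulation practice)
        or on raw values.
        """
        pts = self.points
        moran = moran_test(pts.z, pts.u, mode=moran_mode, seed=seed)
        if not moran.significant:
            warnings.warn(
                "no significant spatial autocorrelation (Moran p = "
                f"{moran.p:.3g} >= {SIGNIFICANCE_ALPHA}): interpolated maps are "
                "not statistically supported",
                stacklevel=2,
            )

        scores, ns_map = normal_score(pts.z)
        ns_points = PointSamples(u=pts.u, z=scores)
        if fit_variogram_on == "scores":
            variogram = fit_exponential(semivariogram_cloud(ns_points))
        elif fit_variogram_on == "raw":
            variogram = fit_exponential(semivariogram_cloud(pts))
        else:
            raise ValidationError("fit_variogram_on must be 'scores' or 'raw'")

        ensemble = run_ensemble(
            ns_points,
            variogram if fit_variogram_on == "scores" else _rescaled_for_scores(variogram, ns_points),
            self.grid,
            n_real=n_realizations,
            master_seed=seed,
            k_neighbors=k_neighbors,
            normal_score_map=ns_map,
            value_floor=0.0,
        )

        cv_report = None
        if cv is not None:
            raw_model = (
                variogram if fit_variogram_on == "raw"
                else fit_exponential(semivariogram_cloud(pts))
            )
            cv_report = loo_cross_validate(pts, raw_model, predictor=cv, seed=seed)

        return DiffusionMapResults(
            model=self,
            variogram=variogram,
            normal_score_map=ns_map,
            moran=moran,
            ensemble=ensemble,
            cv=cv_report,
            seed=seed,
        )


def _rescaled_for_scores(model: VariogramModel, ns_points: PointSamples) -> VariogramModel:
    """Reuse a raw-space variogram's range for the (unit-variance) score space."""
    scale = float(np.var(ns_points.z)) / model.c if model.c > 0 else 1.0
    return VariogramModel(a=model.a, b=model.b * scale, c=model.c * scale)


@dataclass
class DiffusionMapResults:
    """Fitted whole-cell diffusion map: estimates, uncertainty, diagnostics."""

    model: DiffusionMap
    variogram: VariogramModel
    normal_score_map: NormalScoreMap
    moran: MoranResult
    ensemble: SgsEnsemble
    cv: CvReport | None
    seed: int

    @property
    def mean_map(self) -> np.ndarray:
        """Per-node ensemble mean in um^2/s (NaN outside the cell)."""
        return self.ensemble.mean_map

    @property
    def spread_map(self) -> np.ndarray:
        """Per-node ensemble standard deviation (prediction spread)."""
        return self.ensemble.sd_map

    def kriging_map(self):
        """The single best-estimate surface by plain ordinary kriging (raw space)."""
        pts = self.model.points
        raw_model = fit_exponential(semivariogram_cloud(pts))
        return krige_map(pts, raw_model, self.model.grid)

    def plot(self, ax=None, which: str = "mean", **imshow_kwargs):
        """Render the mean or spread map with measurement points overlaid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        data = self.mean_map if which == "mean" else self.spread_map
        grid = self.model.grid
        extent = (0, grid.shape[1] * grid.pitch[0], grid.shape[0] * grid.pitch[1], 0)
        im = ax.imshow(data, extent=extent, **imshow_kwargs)
        ax.scatter(*self.model.points.u.T, s=10, c="white", edgecolors="k", linewidths=0.4)
        ax.set_xlabel("x (um)")
        ax.set_ylabel("y (um)")
        ax.figure.colorbar(im, ax=ax, label="D (um$^2$/s)" if which == "mean" else "SD")
        return ax

    def summary(self) -> str:
        pts = self.model.points
        lines = [
            "Whole-cell diffusion map (variogram + sequential Gaussian simulation)",
            "=" * 70,
            f"measurement points        {len(pts)}",
            f"grid nodes (in cell)      {self.model.grid.n_nodes}  "
            f"shape {self.model.grid.shape}, pitch {self.model.grid.pitch[0]:.3g} um",
            f"realizations              {self.ensemble.n_real}  (master seed {self.seed})",
            "",
            "Spatial structure (exponential variogram, normal-score space)",
            f"  range a                 {self.variogram.a:.4g} um",
            f"  nugget b                {self.variogram.b:.4g}",
            f"  sill c                  {self.variogram.c:.4g}",
            "",
            "Spatial autocorrelation (Moran's I, inverse-square weights)",
            f"  I                       {self.moran.I:.4f}",
            f"  E[I] under null         {self.moran.expected_I:.4f}",
            f"  z                       {self.moran.z:.3f}",
            f"  p ({self.moran.mode})          {self.moran.p:.3g}"
            + ("  *significant*" if self.moran.significant else "  (not significant)"),
            "",
            "Mapped diffusivity (um^2/s)",
            f"  data   min/median/max   {pts.z.min():.3g} / {np.median(pts.z):.3g} / {pts.z.max():.3g}",
            f"  map    min/median/max   {np.nanmin(self.mean_map):.3g} / "
            f"{np.nanmedian(self.mean_map):.3g} / {np.nanmax(self.mean_map):.3g}",
            f"  spread mean             {self.ensemble.sd_values.mean():.3g}",
        ]
        if self.cv is not None:
            lines += [
                "",
                f"Leave-one-out cross-validation ({self.cv.method})",
                f"  accuracy                {self.cv.accuracy_percent:.1f}%",
                f"  MAE / RMSE              {self.cv.mae:.3g} / {self.cv.rmse:.3g}",
            ]
        return "\n".join(lines)

    def report_dict(self) -> dict:
        """JSON-serializable provenance + diagnostics record."""
        d = {
            "n_points": len(self.model.points),
            "n_nodes": self.model.grid.n_nodes,
            "grid_shape": list(self.model.grid.shape),
            "n_realizations": self.ensemble.n_real,
            "master_seed": self.seed,
            "realization_seeds": self.ensemble.realization_seeds.tolist(),
            "variogram": {"a_um": self.variogram.a, "b": self.variogram.b, "c": self.variogram.c},
            "moran": {
                "I": self.moran.I, "expected_I": self.moran.expected_I,
                "z": self.moran.z, "p": self.moran.p, "mode": self.moran.mode,
                "significant": self.moran.significant,
            },
        }
        if self.cv is not None:
            d["cv"] = {
                "method": self.cv.method,
                "accuracy_percent": self.cv.accuracy_percent,
                "mae": self.cv.mae,
                "rmse": self.cv.rmse,
            }
        return d
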