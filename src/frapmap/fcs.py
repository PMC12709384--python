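"""Fluorescence correlation spectroscopy: intensity ACF and dual-component fit.

The normalized fluctuation autocorrelation of an intensity trace F(t) is

    G(tau) = <dF(t) dF(t + tau)> / <F>^2,     dF = F - <F>.

For two independently diffusing species in a 3-D Gaussian confocal volume
with lateral waist w_xy and structure parameter S (axial/lateral ratio):

    G(tau) = sum_i N_i^-1 (1 + tau/tau_Di)^-1 (1 + tau/(S^2 tau_Di))^-1/2

and each characteristic time maps to a diffusion coefficient through

    D_i = w_xy^2 / (4 tau_Di).

N_i is the mean number of molecules of component i in the focal volume
(its reciprocal is the component's amplitude at tau -> 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .exceptions import InsufficientDataError, ValidationError

__all__ = [
    "IntensityTrace",
    "AcfCurve",
    "DualComponentFit",
    "compute_acf",
    "fit_dual_component",
    "dual_component_model",
    "diffusion_from_tau",
    "quasi_log_lags",
]


@dataclass(frozen=True)
class IntensityTrace:
    """Fluorescence samples F at fixed interval dt (s)."""

    F: np.ndarray
    dt: float

    def __post_init__(self):
        F = np.asarray(self.F, dtype=float)
        if F.ndim != 1 or F.size < 2:
            raise ValidationError("trace must be a 1-D array with >= 2 samples")
        if not np.all(np.isfinite(F)) or np.any(F < 0):
            raise ValidationError("trace must be finite and non-negative")
        if self.dt <= 0:
            raise ValidationError("sampling interval must be positive")
        object.__setattr__(self, "F", F)

    @property
    def duration(self) -> float:
        return self.F.size * self.dt


@dataclass(frozen=True)
class AcfCurve:
    tau: np.ndarray
    G: np.ndarray

    def __post_init__(self):
        tau = np.asarray(self.tau, dtype=float)
        G = np.asarray(self.G, dtype=float)
        if tau.shape != G.shape or tau.ndim != 1:
            raise ValidationError("tau and G must be equal-length vectors")
        if np.any(tau <= 0) or np.any(np.diff(tau) <= 0):
            raise ValidationError("lags must be positive and strictly increasing")
        object.__setattr__(self, "tau", tau)
        object.__setattr__(self, "G", G)


@dataclass(frozen=True)
class DualComponentFit:
    """Two-component 3-D diffusion fit; components ordered tauD1 < tauD2."""

    N1: float
    N2: float
    tauD1: float
    tauD2: float
    w_xy: float
    S: float
    D1: float
    D2: float
    residual_ss: float
    converged: bool


def quasi_log_lags(dt: float, max_lag: float, points_per_decade: int = 12) -> np.ndarray:
    """Multi-tau-style quasi-logarithmic lag grid in integer multiples of dt."""
    if max_lag <= dt:
        raise ValidationError("max_lag must exceed the sampling interval")
    n_dec = np.log10(max_lag / dt)
    raw = dt * 10 ** np.linspace(0, n_dec, max(int(np.ceil(n_dec * points_per_decade)), 2))
    k = np.unique(np.round(raw / dt).astype(int))
    k = k[k >= 1]
    return k * dt


def compute_acf(trace: IntensityTrace, lags=None) -> AcfCurve:
    """Normalized fluctuation autocorrelation at the requested lags.

    ``lags`` may be lag times (s, rounded to sample multiples) or omitted
    for the default quasi-log grid up to a quarter of the trace duration.
    Each G(tau) averages dF(t) dF(t+tau) over all valid t.
    """
    F = trace.F
    mean = F.mean()
    if mean <= 0:
        raise ValidationError("zero-mean trace: ACF normalization undefined")
    if lags is None:
        lags = quasi_log_lags(trace.dt, trace.duration / 4.0)
    lags = np.asarray(lags, dtype=float)
    if np.any(lags >= trace.duration / 2.0):
        raise ValidationError("lags must be below half the trace duration")
    ks = np.round(lags / trace.dt).astype(int)
    if np.any(ks < 1):
        raise ValidationError("lags must be at least one sampling interval")
    dF = F - mean
    G = np.array([np.mean(dF[: F.size - k] * dF[k:]) for k in ks]) / mean**2
    return AcfCurve(tau=ks * trace.dt, G=G)


def dual_component_model(tau, N1, N2, tauD1, tauD2, S):
    tau = np.asarray(tau, dtype=float)
    g1 = (1.0 / N1) / (1.0 + tau / tauD1) / np.sqrt(1.0 + tau / (S**2 * tauD1))
    g2 = (1.0 / N2) / (1.0 + tau / tauD2) / np.sqrt(1.0 + tau / (S**2 * tauD2))
    return g1 + g2


def diffusion_from_tau(w_xy: float, tau_D: float) -> float:
    """D = w_xy^2 / (4 tau_D)."""
    if w_xy <= 0 or tau_D <= 0:
        raise ValidationError("w_xy and tau_D must be positive")
    return w_xy**2 / (4.0 * tau_D)


def fit_dual_component(
    acf: AcfCurve, w_xy: float = 0.21, S: float = 2.67, weights: str = "uniform"
) -> DualComponentFit:
    """Least-squares fit of the two-component diffusion model to an ACF.

    ``w_xy`` (um) and ``S`` are instrument calibration constants (defaults
    from a rhodamine-B calibration of a confocal setup).  Components are
    ordered so tauD1 < tauD2 (fast first).  ``weights="inverse"`` weights
    residuals by 1/|G| instead of uniformly.
    """
    if len(acf.tau) < 8:
        raise InsufficientDataError("need at least 8 ACF lags for a 4-parameter fit")
    if w_xy <= 0 or S <= 0:
        raise ValidationError("w_xy and S must be positive")
    tau, G = acf.tau, acf.G
    w = 1.0 / np.maximum(np.abs(G), 1e-12) if weights == "inverse" else np.ones_like(G)

    g0 = max(float(G[0]), 1e-9)
    # split amplitude evenly, timescales bracketing the lag range
    x0 = np.log([2.0 / g0, 2.0 / g0, tau[0] * 3.0, tau[-1] / 3.0])

    def resid(x):
        N1, N2, t1, t2 = np.exp(x)
        return w * (dual_component_model(tau, N1, N2, t1, t2, S) - G)

    sol = least_squares(resid, x0=x0, method="lm", max_nfev=20000)
    N1, N2, t1, t2 = np.exp(sol.x)
    if t1 > t2:
        N1, N2, t1, t2 = N2, N1, t2, t1
    return DualComponentFit(
        N1=float(N1), N2=float(N2), tauD1=float(t1), tauD2=float(t2),
        w_xy=float(w_xy), S=float(S),
        D1=diffusion_from_tau(w_xy, t1), D2=diffusion_from_tau(w_xy, t2),
        residual_ss=float(np.sum(sol.fun**2)),
        converged=bool(sol.success),
    )
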