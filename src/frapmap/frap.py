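"""Diffusion-coefficient estimation from FRAP image time series.

After photobleaching a small circular region, fluorescence recovers as
unbleached molecules diffuse in.  For a Gaussian bleach profile the radial
intensity distribution around the spot center evolves as

    F(r, t) = A1 - A2 / (4 D t + rho^2) * exp(-r^2 / (4 D t + rho^2))

where D is the diffusion coefficient (um^2/s), A1 the recovered plateau
intensity, A2 the bleach depth scale (intensity * um^2) and rho the initial
bleach radius scale (um).  Fitting this model jointly over all post-bleach
frames and radii by least squares yields D per bleach spot.

The workflow is: global photobleaching correction (simple-ratio against a
non-bleached reference region), radial binning of intensity around each
spot, then the joint spatiotemporal fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .exceptions import InsufficientDataError, ValidationError
from .variogram import PointSamples

__all__ = [
    "FrapStack",
    "BleachSpot",
    "RecoveryFit",
    "correct_photobleaching",
    "radial_profile",
    "fit_recovery",
    "fit_all_spots",
    "recovery_model",
]


@dataclass(frozen=True)
class FrapStack:
    """A FRAP acquisition: (time, row, col) intensity frames plus geometry.

    ``n_prebleach`` frames precede the bleach; recovery imaging starts at
    ``bleach_end_index`` (so frames in between are the bleach phase).
    """

    frames: np.ndarray
    pixel_size: float
    frame_interval: float
    n_prebleach: int = 2
    bleach_end_index: int = 3

    def __post_init__(self):
        frames = np.asarray(self.frames, dtype=float)
        if frames.ndim != 3:
            raise ValidationError("frames must be a 3-D (time, row, col) array")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValidationError("pixel_size and frame_interval must be positive")
        if self.n_prebleach < 1:
            raise ValidationError("need at least one pre-bleach frame")
        if self.bleach_end_index <= self.n_prebleach:
            raise ValidationError("bleach_end_index must exceed n_prebleach")
        if frames.shape[0] - self.bleach_end_index < 3:
            raise ValidationError("need at least 3 recovery frames")
        if np.any(frames < 0):
            raise ValidationError("frame intensities must be non-negative")
        object.__setattr__(self, "frames", frames)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def recovery_indices(self) -> np.ndarray:
        return np.arange(self.bleach_end_index, self.n_frames)

    def recovery_times(self, t_origin: float | None = None) -> np.ndarray:
        """Times (s) of recovery frames measured from the end of bleach.

        Default origin places t = half a frame interval at the first
        recovery frame (the bleach happens during the preceding interval).
        """
        if t_origin is None:
            t_origin = 0.5 * self.frame_interval
        return t_origin + (self.recovery_indices - self.bleach_end_index) * self.frame_interval


@dataclass(frozen=True)
class BleachSpot:
    """A photobleached circular region: center (x, y) in um, nominal diameter um."""

    center: tuple
    nominal_diameter: float = 3.0

    def __post_init__(self):
        if self.nominal_diameter <= 0:
            raise ValidationError("spot diameter must be positive")
        object.__setattr__(self, "center", (float(self.center[0]), float(self.center[1])))

    @property
    def radius(self) -> float:
        return self.nominal_diameter / 2.0


@dataclass(frozen=True)
class RecoveryFit:
    """Fitted recovery-model parameters for one bleach spot."""

    D: float
    A1: float
    A2: float
    rho: float
    residual_ss: float
    converged: bool
    message: str = ""


def recovery_model(r, t, D, A1, A2, rho):
    """The Gaussian recovery profile F(r, t)."""
    s = 4.0 * D * t + rho**2
    return A1 - A2 / s * np.exp(-np.asarray(r) ** 2 / s)


def _check_spot_in_bounds(stack: FrapStack, spot: BleachSpot):
    nrow, ncol = stack.frames.shape[1:]
    x, y = spot.center
    if not (0 <= x <= (ncol - 1) * stack.pixel_size and 0 <= y <= (nrow - 1) * stack.pixel_size):
        raise ValidationError(f"spot center {spot.center} outside image bounds")


def correct_photobleaching(stack: FrapStack, reference_mask, bleach_spots=()) -> FrapStack:
    """Simple-ratio photobleaching correction.

    Each frame is multiplied by ref_mean(prebleach) / ref_mean(frame), where
    the reference mean is taken over ``reference_mask`` (nonzero = reference,
    must not overlap any declared bleach spot).  A global multiplicative
    decay is removed exactly by this ratio.
    """
    mask = np.asarray(reference_mask) != 0
    if mask.shape != stack.frames.shape[1:]:
        raise ValidationError("reference mask shape does not match frames")
    if not mask.any():
        raise ValidationError("reference mask is empty")
    rr, cc = np.nonzero(mask)
    xs, ys = cc * stack.pixel_size, rr * stack.pixel_size
    for spot in bleach_spots:
        d = np.hypot(xs - spot.center[0], ys - spot.center[1])
        if np.any(d <= spot.radius):
            raise ValidationError("reference mask overlaps a declared bleach spot")
    ref = stack.frames[:, mask].mean(axis=1)
    if np.any(ref <= 0):
        raise ValidationError("degenerate reference: zero mean intensity in a frame")
    # normalize to the first (pre-bleach) frame: a global multiplicative
    # decay is then removed exactly
    corrected = stack.frames * (ref[0] / ref)[:, None, None]
    return FrapStack(
        frames=corrected,
        pixel_size=stack.pixel_size,
        frame_interval=stack.frame_interval,
        n_prebleach=stack.n_prebleach,
        bleach_end_index=stack.bleach_end_index,
    )


def radial_profile(
    stack: FrapStack,
    spot: BleachSpot,
    frame_index: int,
    bin_width: float | None = None,
    max_radius: float | None = None,
):
    """Radially binned mean intensity around a spot center for one frame.

    Bins have fixed width (default one pixel in um) out to ``max_radius``
    (default 2x the spot radius).  Returns (r um, mean intensity) with r the
    mean radius of the pixels in each bin (not the nominal bin center, which
    would bias model fits at the profile's curved core); empty bins are
    omitted.  A spot too close to the image edge triggers a truncation
    warning, not an error.
    """
    _check_spot_in_bounds(stack, spot)
    if frame_index < stack.bleach_end_index - 1 or frame_index >= stack.n_frames:
        raise ValidationError("frame_index outside the bleach/recovery phase")
    if bin_width is None:
        bin_width = stack.pixel_size
    if max_radius is None:
        max_radius = 2.0 * spot.radius
    nrow, ncol = stack.frames.shape[1:]
    x = np.arange(ncol) * stack.pixel_size - spot.center[0]
    y = np.arange(nrow) * stack.pixel_size - spot.center[1]
    r = np.hypot(x[None, :], y[:, None])
    xmax = (ncol - 1) * stack.pixel_size
    ymax = (nrow - 1) * stack.pixel_size
    edge_dist = min(spot.center[0], spot.center[1], xmax - spot.center[0], ymax - spot.center[1])
    if edge_dist < max_radius:
        warnings.warn(
            "spot closer to the image edge than max_radius: outer bins truncated",
            stacklevel=2,
        )
    n_bins = int(np.ceil(max_radius / bin_width))
    sel = r <= max_radius
    idx = np.clip((r[sel] / bin_width).astype(int), 0, n_bins - 1)
    vals = stack.frames[frame_index][sel]
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=vals, minlength=n_bins)
    rsums = np.bincount(idx, weights=r[sel], minlength=n_bins)
    nonempty = counts > 0
    return rsums[nonempty] / counts[nonempty], sums[nonempty] / counts[nonempty]


def fit_recovery(profiles, t_origin: float = 0.0, p0: dict | None = None) -> RecoveryFit:
    """Joint least-squares fit of the recovery model over all (r, t) samples.

    ``profiles`` is a sequence of (t, r_array, F_array) triples with t in
    seconds measured from the end of bleach (plus ``t_origin``).  D is
    constrained >= 0 and rho > 0.  Optimizer failure or a non-identifiable
    bleach signature yields ``converged=False`` rather than an exception.
    """
    ts, rs, fs = [], [], []
    for t, r, f in profiles:
        r = np.asarray(r, dtype=float)
        f = np.asarray(f, dtype=float)
        ts.append(np.full(r.size, float(t) + t_origin))
        rs.append(r)
        fs.append(f)
    if len(ts) < 3:
        raise InsufficientDataError("need at least 3 post-bleach time points")
    t = np.concatenate(ts)
    r = np.concatenate(rs)
    f = np.concatenate(fs)
    if f.size < 4:
        raise InsufficientDataError("need at least 4 samples to identify 4 parameters")

    if p0 is None:
        p0 = {}
    A1_0 = p0.get("A1", float(np.percentile(f, 90)))
    rho_0 = p0.get("rho", max(float(np.median(r)), 1e-3))
    # bleach depth from the deepest central dip
    center = r <= np.percentile(r, 25)
    depth = max(A1_0 - float(f[center].min()), 1e-6 * max(abs(A1_0), 1.0))
    A2_0 = p0.get("A2", depth * rho_0**2)
    # recovery half-time from the central dip trajectory
    D_0 = p0.get("D")
    if D_0 is None:
        tu = np.unique(t)
        c_traj = np.array([f[(t == tt) & center].mean() for tt in tu])
        half = c_traj[0] + 0.5 * (A1_0 - c_traj[0])
        above = np.nonzero(c_traj >= half)[0]
        t_half = tu[above[0]] if above.size else tu[-1]
        D_0 = rho_0**2 / (4.0 * max(t_half, tu[0]))

    def resid(theta):
        D, A1, A2, rho = theta
        return recovery_model(r, t, D, A1, A2, rho) - f

    try:
        sol = least_squares(
            resid,
            x0=[max(D_0, 1e-6), A1_0, A2_0, rho_0],
            bounds=([0.0, -np.inf, -np.inf, 1e-6], [np.inf, np.inf, np.inf, np.inf]),
            method="trf",
        )
    except Exception as exc:
        return RecoveryFit(
            D=np.nan, A1=np.nan, A2=np.nan, rho=np.nan,
            residual_ss=np.nan, converged=False, message=str(exc),
        )
    D, A1, A2, rho = sol.x
    rss = float(np.sum(sol.fun**2))
    # D is only identifiable if the fit actually tracks a bleach signature:
    # require the fitted central depth at the earliest frame to exceed 0.1%
    # of the plateau (anything smaller is background structure, not a bleach)
    t_min = float(t.min())
    depth_fit = abs(A2) / (4.0 * D * t_min + rho**2)
    identifiable = depth_fit > 1e-3 * max(abs(A1), 1e-300)
    return RecoveryFit(
        D=float(D), A1=float(A1), A2=float(A2), rho=float(rho),
        residual_ss=rss,
        converged=bool(sol.success and identifiable),
        message="" if sol.success else sol.message,
    )


def fit_all_spots(
    stack: FrapStack,
    spots,
    t_origin: float | None = None,
    bin_width: float | None = None,
    max_radius: float | None = None,
) -> tuple[PointSamples, list]:
    """Fit every bleach spot and collect converged fits as point samples.

    Returns ``(points, records)`` where ``points`` holds (x, y, D) for the
    converged spots and ``records`` one ``(spot, RecoveryFit)`` pair per
    spot, including the excluded (non-converged) ones.

    Fitting uses quarter-pixel radial bins by default: each bin then spans
    a near-constant radius, so the binned profile carries no curvature bias
    into the least-squares fit (the coarser one-pixel default of
    :func:`radial_profile` is meant for display).
    """
    spots = list(spots)
    if not spots:
        raise ValidationError("empty spot list")
    times = stack.recovery_times(t_origin)
    if bin_width is None:
        bin_width = stack.pixel_size / 4.0
    records = []
    xs, ys, ds = [], [], []
    for spot in spots:
        profiles = []
        for t, fi in zip(times, stack.recovery_indices):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                r, f = radial_profile(stack, spot, int(fi), bin_width=bin_width, max_radius=max_radius)
            profiles.append((float(t), r, f))
        fit = fit_recovery(profiles, t_origin=0.0)
        records.append((spot, fit))
        if fit.converged:
            xs.append(spot.center[0])
            ys.append(spot.center[1])
            ds.append(fit.D)
    if not ds:
        raise ValidationError("no bleach spot produced a converged fit")
    n_failed = len(spots) - len(ds)
    if n_failed:
        warnings.warn(f"{n_failed} spot(s) excluded (non-converged fit)", stacklevel=2)
    return PointSamples(u=np.column_stack([xs, ys]), z=np.asarray(ds)), records
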