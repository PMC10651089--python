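"""Gaussian fitting of detected features and field-of-view summaries.

Each accepted peak is measured twice: a 2D elliptical Gaussian is fitted to a
circularly masked lateral patch in the peak's plane, and a 1D Gaussian to the
axial intensity profile through the peak.  Widths are converted to FWHM with
the Gaussian relation FWHM = 2*sqrt(2 ln 2) * sigma (~2.355 sigma) and, when
the voxel calibration is known, expressed in nanometres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .detection import FeaturePeak
from .errors import DomainError
from .stack_io import ImageStack

#: FWHM of a Gaussian in units of sigma
FWHM_FACTOR: float = 2.0 * math.sqrt(2.0 * math.log(2.0))

DEFAULT_PATCH_RADIUS = 5
SIGMA_MIN_PX = 0.5
_BOUND_TOL = 1e-3


@dataclass(frozen=True)
class GaussianFit2D:
    """Elliptical 2D Gaussian fit of one lateral patch.

    ``theta`` is the orientation of the major axis relative to the image X
    axis, canonicalised to (-pi/2, pi/2]; ``sigma_major >= sigma_minor``.
    """

    center_y: float
    center_x: float
    sigma_major: float
    sigma_minor: float
    theta: float
    amplitude: float
    offset: float
    r_squared: float


@dataclass(frozen=True)
class GaussianFit1D:
    center_z: float
    sigma_z: float
    amplitude: float
    offset: float
    r_squared: float


@dataclass
class FeatureMeasurement:
    """All measured quantities of one detected feature."""

    peak: FeaturePeak
    status: str = "ok"  # ok | fit_failed | edge_rejected
    fit_xy: Optional[GaussianFit2D] = None
    fit_z: Optional[GaussianFit1D] = None
    fwhm_max_px: Optional[float] = None
    fwhm_min_px: Optional[float] = None
    fwhm_x_px: Optional[float] = None
    fwhm_y_px: Optional[float] = None
    fwhm_z_px: Optional[float] = None
    fwhm_max_nm: Optional[float] = None
    fwhm_min_nm: Optional[float] = None
    fwhm_x_nm: Optional[float] = None
    fwhm_y_nm: Optional[float] = None
    fwhm_z_nm: Optional[float] = None


class FitError(Exception):
    """Internal signal that a Gaussian fit did not produce a usable result."""


def sigma_to_fwhm(sigma: float, pixel_size: Optional[float] = None) -> tuple[float, str]:
    """Convert a Gaussian sigma to FWHM.

    Returns ``(fwhm, unit)`` where the unit is ``"nm"`` when a pixel size in
    nm is given and ``"px"`` otherwise.
    """
    if not (sigma > 0):
        raise DomainError(f"sigma must be positive, got {sigma}")
    if pixel_size is None:
        return FWHM_FACTOR * sigma, "px"
    if not (pixel_size > 0):
        raise DomainError(f"pixel size must be positive, got {pixel_size}")
    return FWHM_FACTOR * sigma * pixel_size, "nm"


def circular_mask(radius: int) -> np.ndarray:
    """Boolean disc selecting the pixels of a ``(2r+1) x (2r+1)`` patch
    covered by a circle of the given radius: a pixel (unit square) belongs to
    the disc when its centre lies within ``radius + 1/2`` (97 pixels for
    radius 5)."""
    yy, xx = np.mgrid[-radius:radius + 1, -radius:radius + 1]
    r = radius + 0.5
    return yy * yy + xx * xx <= r * r


def extract_patches(
    stack: ImageStack, peak: FeaturePeak, radius: int = DEFAULT_PATCH_RADIUS
) -> tuple[np.ma.MaskedArray, np.ndarray]:
    """Lateral patch (masked outside the fitting disc) and full axial profile.

    Raises :class:`FitError` with an ``edge_rejected`` message when the patch
    would leave the lateral image bounds or the peak sits on the first/last
    plane.
    """
    nz, ny, nx = stack.shape
    z, y, x = peak.z, peak.y, peak.x
    if (y - radius < 0 or y + radius >= ny or x - radius < 0 or x + radius >= nx
            or z < 1 or z > nz - 2):
        raise FitError("edge_rejected")
    patch = stack.data[z, y - radius:y + radius + 1, x - radius:x + radius + 1]
    masked = np.ma.MaskedArray(patch, mask=~circular_mask(radius))
    profile = stack.data[:, y, x].copy()
    return masked, profile


def _r_squared(values: np.ndarray, model: np.ndarray) -> float:
    ss_res = float(np.sum((values - model) ** 2))
    ss_tot = float(np.sum((values - values.mean()) ** 2))
    if ss_tot == 0:
        return -math.inf if ss_res > 0 else 1.0
    return 1.0 - ss_res / ss_tot


def _gauss2d(coords, offset, amp, y0, x0, sa, sb, theta):
    yy, xx = coords
    ct, st = np.cos(theta), np.sin(theta)
    u = (xx - x0) * ct + (yy - y0) * st
    v = -(xx - x0) * st + (yy - y0) * ct
    return offset + amp * np.exp(-(u * u / (2 * sa * sa) + v * v / (2 * sb * sb)))


def fit_gaussian_2d(patch: np.ma.MaskedArray, init_sigma: float) -> GaussianFit2D:
    """Least-squares elliptical Gaussian fit of a masked lateral patch.

    Raises :class:`FitError` on non-convergence, vanishing amplitude, or a
    width pinned at the bounds (degenerate plateau).
    """
    patch = np.ma.asarray(patch, dtype=float)
    valid = ~np.ma.getmaskarray(patch)
    n_valid = int(valid.sum())
    if n_valid < 8:
        raise FitError("fewer than 8 unmasked pixels")
    ny, nx = patch.shape
    radius = (min(ny, nx) - 1) / 2.0
    yy, xx = np.mgrid[0:ny, 0:nx]
    yv, xv = yy[valid].astype(float), xx[valid].astype(float)
    zv = np.asarray(patch.data)[valid].astype(float)
    if np.ptp(zv) == 0:
        raise FitError("flat patch")

    border = zv[np.hypot(yv - (ny - 1) / 2, xv - (nx - 1) / 2) >= radius - 1.0]
    offset0 = float(np.median(border)) if border.size else float(zv.min())
    amp0 = max(float(zv.max()) - offset0, 1e-12)
    s0 = float(np.clip(init_sigma, SIGMA_MIN_PX, radius))
    p0 = [offset0, amp0, (ny - 1) / 2.0, (nx - 1) / 2.0, s0, s0, 0.0]
    lb = [-np.inf, 0.0, -1.0, -1.0, SIGMA_MIN_PX, SIGMA_MIN_PX, -math.pi]
    ub = [np.inf, np.inf, ny, nx, radius, radius, math.pi]

    def residuals(p):
        return _gauss2d((yv, xv), *p) - zv

    sol = least_squares(residuals, p0, bounds=(lb, ub), method="trf")
    if not sol.success:
        raise FitError("optimizer did not converge")
    offset, amp, y0, x0, sa, sb, theta = sol.x
    for s in (sa, sb):
        if s <= SIGMA_MIN_PX + _BOUND_TOL or s >= radius - _BOUND_TOL:
            raise FitError("width pinned at bound")
    if amp <= _BOUND_TOL * max(abs(offset), 1.0):
        raise FitError("vanishing amplitude")

    # canonical orientation: theta refers to the major axis, in (-pi/2, pi/2]
    if sb > sa:
        sa, sb = sb, sa
        theta += math.pi / 2
    theta = math.remainder(theta, math.pi)
    if theta <= -math.pi / 2:
        theta += math.pi
    elif theta > math.pi / 2:
        theta -= math.pi

    model = _gauss2d((yv, xv), offset, amp, y0, x0, sa, sb, theta)
    return GaussianFit2D(
        center_y=float(y0), center_x=float(x0),
        sigma_major=float(sa), sigma_minor=float(sb), theta=float(theta),
        amplitude=float(amp), offset=float(offset),
        r_squared=_r_squared(zv, model),
    )


def _gauss1d(z, offset, amp, z0, sz):
    return offset + amp * np.exp(-((z - z0) ** 2) / (2 * sz * sz))


def fit_gaussian_1d(profile: Sequence[float], init_sigma: float) -> GaussianFit1D:
    """Least-squares 1D Gaussian fit of an axial intensity profile."""
    prof = np.asarray(profile, dtype=float).ravel()
    n = prof.size
    if n < 5:
        raise DomainError("axial profile needs at least 5 samples")
    if np.ptp(prof) == 0:
        raise FitError("constant profile")
    z = np.arange(n, dtype=float)
    z0_init = float(np.argmax(prof))
    offset0 = float(np.median(np.concatenate([prof[:2], prof[-2:]])))
    amp0 = max(float(prof.max()) - offset0, 1e-12)
    smax = n / 2.0
    s0 = float(np.clip(init_sigma, SIGMA_MIN_PX, smax))
    p0 = [offset0, amp0, z0_init, s0]
    lb = [-np.inf, 0.0, -1.0, SIGMA_MIN_PX]
    ub = [np.inf, np.inf, float(n), smax]

    def residuals(p):
        return _gauss1d(z, *p) - prof

    sol = least_squares(residuals, p0, bounds=(lb, ub), method="trf")
    if not sol.success:
        raise FitError("optimizer did not converge")
    offset, amp, z0, sz = sol.x
    if sz <= SIGMA_MIN_PX + _BOUND_TOL or sz >= smax - _BOUND_TOL:
        raise FitError("width pinned at bound")
    if amp <= 0:
        raise FitError("vanishing amplitude")
    model = _gauss1d(z, offset, amp, z0, sz)
    return GaussianFit1D(
        center_z=float(z0), sigma_z=float(sz),
        amplitude=float(amp), offset=float(offset),
        r_squared=_r_squared(prof, model),
    )


def measure_feature(
    stack: ImageStack,
    peak: FeaturePeak,
    init_sigma: float,
    radius: int = DEFAULT_PATCH_RADIUS,
) -> FeatureMeasurement:
    """Fit one peak laterally and axially and derive all FWHM quantities.

    Returns a measurement whose ``status`` records edge rejection or fit
    failure instead of raising.  Lateral widths are converted to nm with the
    X pixel size (lateral pixels are assumed square); the axial width with the
    z step.  Absent calibration leaves the nm fields absent.
    """
    from .ellipse_geometry import fwhm_xy_from_ellipse

    m = FeatureMeasurement(peak=peak)
    try:
        patch, profile = extract_patches(stack, peak, radius)
    except FitError:
        m.status = "edge_rejected"
        return m
    try:
        m.fit_xy = fit_gaussian_2d(patch, init_sigma)
        m.fit_z = fit_gaussian_1d(profile, init_sigma)
    except (FitError, DomainError):
        m.status = "fit_failed"
        return m

    m.fwhm_max_px, _ = sigma_to_fwhm(m.fit_xy.sigma_major)
    m.fwhm_min_px, _ = sigma_to_fwhm(m.fit_xy.sigma_minor)
    m.fwhm_x_px, m.fwhm_y_px = fwhm_xy_from_ellipse(
        m.fwhm_max_px, m.fwhm_min_px, m.fit_xy.theta
    )
    m.fwhm_z_px, _ = sigma_to_fwhm(m.fit_z.sigma_z)

    cal = stack.calibration
    if cal.dx is not None:
        m.fwhm_max_nm = m.fwhm_max_px * cal.dx
        m.fwhm_min_nm = m.fwhm_min_px * cal.dx
        m.fwhm_x_nm = m.fwhm_x_px * cal.dx
        m.fwhm_y_nm = m.fwhm_y_px * cal.dx
    if cal.dz is not None:
        m.fwhm_z_nm = m.fwhm_z_px * cal.dz
    return m


# ---------------------------------------------------------------------------
# field summaries

_SUMMARY_PARAMS = (
    "fwhm_max", "fwhm_min", "fwhm_x", "fwhm_y", "fwhm_z",
)


@dataclass
class FieldSummary:
    """Across-field means and per-feature table of the fitted parameters."""

    count: int
    n_failed: int
    means_nm: dict
    stds_nm: dict
    means_px: dict
    stds_px: dict
    mean_r2_xy: Optional[float]
    mean_r2_z: Optional[float]
    table: pd.DataFrame
    heatmaps: dict = field(default_factory=dict)


def _mean_std(values: list[float]) -> tuple[Optional[float], Optional[float]]:
    if not values:
        return None, None
    mean = float(np.mean(values))
    std = float(np.std(values, ddof=1)) if len(values) > 1 else None
    return mean, std


def measurement_table(measurements: Sequence[FeatureMeasurement]) -> pd.DataFrame:
    """Per-feature table in detection order (row index = overlay number)."""
    rows = []
    for i, m in enumerate(measurements):
        row: dict = {
            "index": i,
            "x_px": m.peak.x, "y_px": m.peak.y, "z_px": m.peak.z,
            "status": m.status,
        }
        for p in _SUMMARY_PARAMS:
            row[f"{p}_px"] = getattr(m, f"{p}_px")
            row[f"{p}_nm"] = getattr(m, f"{p}_nm")
        row["theta_deg"] = math.degrees(m.fit_xy.theta) if m.fit_xy else None
        row["r2_xy"] = m.fit_xy.r_squared if m.fit_xy else None
        row["r2_z"] = m.fit_z.r_squared if m.fit_z else None
        rows.append(row)
    cols = (["index", "x_px", "y_px", "z_px", "status"]
            + [f"{p}_{u}" for p in _SUMMARY_PARAMS for u in ("nm", "px")]
            + ["theta_deg", "r2_xy", "r2_z"])
    return pd.DataFrame(rows, columns=cols)


def _heatmap(measurements, param: str, shape_yx, grid: int = 8):
    """Mean parameter value per cell of a grid x grid tiling of the field."""
    ny, nx = shape_yx
    acc = np.zeros((grid, grid))
    cnt = np.zeros((grid, grid))
    for m in measurements:
        v = getattr(m, param)
        if m.status != "ok" or v is None:
            continue
        gy = min(int(m.peak.y * grid / ny), grid - 1)
        gx = min(int(m.peak.x * grid / nx), grid - 1)
        acc[gy, gx] += v
        cnt[gy, gx] += 1
    with np.errstate(invalid="ignore"):
        return np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)


def summarize_field(
    measurements: Sequence[FeatureMeasurement],
    shape_yx: Optional[tuple[int, int]] = None,
    heatmap_grid: int = 8,
) -> FieldSummary:
    """Arithmetic mean and sample standard deviation of each fitted parameter
    over features with status ``ok``, plus the per-feature table and coarse
    positional heat-map grids."""
    ok = [m for m in measurements if m.status == "ok"]
    n_failed = sum(1 for m in measurements if m.status != "ok")
    means_nm, stds_nm, means_px, stds_px = {}, {}, {}, {}
    for p in _SUMMARY_PARAMS:
        for unit, means, stds in (("nm", means_nm, stds_nm), ("px", means_px, stds_px)):
            vals = [getattr(m, f"{p}_{unit}") for m in ok]
            vals = [v for v in vals if v is not None]
            means[p], stds[p] = _mean_std(vals)
    r2xy = [m.fit_xy.r_squared for m in ok if m.fit_xy]
    r2z = [m.fit_z.r_squared for m in ok if m.fit_z]
    heatmaps = {}
    if shape_yx is not None:
        for p in _SUMMARY_PARAMS:
            for unit in ("nm", "px"):
                hm = _heatmap(ok, f"{p}_{unit}", shape_yx, heatmap_grid)
                if np.isfinite(hm).any():
                    heatmaps[f"{p}_{unit}"] = hm
    return FieldSummary(
        count=len(ok),
        n_failed=n_failed,
        means_nm=means_nm, stds_nm=stds_nm,
        means_px=means_px, stds_px=stds_px,
        mean_r2_xy=float(np.mean(r2xy)) if r2xy else None,
        mean_r2_z=float(np.mean(r2z)) if r2z else None,
        table=measurement_table(measurements),
        heatmaps=heatmaps,
    )
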