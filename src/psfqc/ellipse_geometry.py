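"""Axis projections of an inclined ellipse.

Elliptical-fit tools describe a spot by its maximum/minimum FWHM and the
inclination theta of the major axis, while other packages report the widths
projected onto the image X and Y axes.  Comparing the two requires projecting
the rotated ellipse onto the axes.  The naive ``2a cos(theta)`` underestimates
the true horizontal extent; the correct projection follows from the boundary
points where the tangent of the rotated ellipse is vertical (gradient
``cot(theta)`` before rotation) or horizontal (``-tan(theta)``).

For an ellipse with semi-axes ``a >= b`` rotated by theta, a boundary point at
parametric angle ``eps`` sits at ``(a cos eps, b sin eps)`` before rotation.
The vertical-tangent condition gives ``tan(eps_x) = -(b/a) tan(theta)``, the
horizontal-tangent condition ``tan(eps_y) = (b/a) cot(theta)``.  The central
chord through the two opposite extreme points has length
``k = 2 sqrt(a^2 cos^2 eps + b^2 sin^2 eps)`` and the projection of that chord
onto the relevant axis is the full extent.  The result equals the closed-form
bounding box of a rotated ellipse, ``X' = 2 sqrt(a^2 cos^2 t + b^2 sin^2 t)``
and ``Y' = 2 sqrt(a^2 sin^2 t + b^2 cos^2 t)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import DomainError


@dataclass(frozen=True)
class RotatedEllipse:
    """Semi-axes ``a >= b > 0`` and inclination of the major axis to X."""

    a: float
    b: float
    theta: float

    def __post_init__(self) -> None:
        if not (self.a >= self.b > 0):
            raise DomainError(f"require a >= b > 0, got a={self.a}, b={self.b}")
        if not math.isfinite(self.theta):
            raise DomainError("theta must be finite")


@dataclass(frozen=True)
class AxisProjection:
    """Full projected widths along X and Y with the solve intermediates."""

    x_extent: float
    y_extent: float
    eps_x: float
    eps_y: float
    k_x: float
    k_y: float


def normalize_theta(theta: float) -> float:
    """Fold an inclination into [0, pi/2].

    The projection of an ellipse is invariant under theta -> -theta and
    theta -> pi - theta, so any angle reduces to the first quadrant: take
    |theta| modulo pi, then reflect angles beyond pi/2 back towards zero.
    """
    if not math.isfinite(theta):
        raise DomainError("theta must be finite")
    t = math.fmod(abs(theta), math.pi)
    if t > math.pi / 2:
        t = math.pi - t
    return t


def _chord(a: float, b: float, eps: float) -> float:
    """Length of the central chord at parametric angle eps (both ends)."""
    return 2.0 * math.hypot(a * math.cos(eps), b * math.sin(eps))


def project_ellipse(e: RotatedEllipse) -> AxisProjection:
    """Full X and Y extents of a rotated ellipse via the tangent conditions."""
    a, b = e.a, e.b
    theta = normalize_theta(e.theta)

    if a == b or theta == 0.0 or theta == math.pi / 2:
        # circle or axis-aligned: the tangent equations degenerate, but the
        # answer is immediate
        if a == b:
            x_ext = y_ext = 2.0 * a
            eps_x, eps_y = 0.0, math.pi / 2
        elif theta == 0.0:
            x_ext, y_ext = 2.0 * a, 2.0 * b
            eps_x, eps_y = 0.0, math.pi / 2
        else:
            x_ext, y_ext = 2.0 * b, 2.0 * a
            eps_x, eps_y = math.pi / 2, 0.0
        return AxisProjection(x_ext, y_ext, eps_x, eps_y,
                              _chord(a, b, eps_x), _chord(a, b, eps_y))

    # vertex parametric angles from the tangent-gradient conditions
    eps_x = math.atan2(-b * math.tan(theta), a)
    eps_y = math.atan2(b, a * math.tan(theta))
    k_x = _chord(a, b, eps_x)
    k_y = _chord(a, b, eps_y)

    cos_t, sin_t = math.cos(theta), math.sin(theta)

    def rotated(eps: float) -> tuple[float, float]:
        u, v = a * math.cos(eps), b * math.sin(eps)
        return u * cos_t - v * sin_t, u * sin_t + v * cos_t

    x_ext = 2.0 * abs(rotated(eps_x)[0])
    y_ext = 2.0 * abs(rotated(eps_y)[1])
    return AxisProjection(x_ext, y_ext, eps_x, eps_y, k_x, k_y)


def fwhm_xy_from_ellipse(fwhm_max: float, fwhm_min: float, theta: float) -> tuple[float, float]:
    """Map a (max, min, theta) FWHM ellipse to X- and Y-axis FWHM widths."""
    if not (fwhm_max >= fwhm_min > 0):
        raise DomainError("require fwhm_max >= fwhm_min > 0")
    proj = project_ellipse(RotatedEllipse(fwhm_max / 2.0, fwhm_min / 2.0, theta))
    return proj.x_extent, proj.y_extent
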