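"""Parameter-free feature detection in 3D bead stacks.

The detector builds a multi-scale representation of the volume: Gaussian-blurred
copies at geometrically spaced kernel widths, differenced between adjacent
scales (a band-pass / difference-of-Gaussians filter), and collapsed by a
maximum-intensity projection along the scale axis.  Local 3D maxima of that
projection above an automatic cross-entropy (Li) threshold are the candidate
features; peaks closer than five pixels laterally are mutually excluded.

With a constant-ratio scale grid the adjacent difference is already
scale-normalised (it approximates ``(k-1) sigma^2 * Laplacian-of-Gaussian``),
so the scale whose difference volume attains the global maximum tracks the blob
width directly; the characteristic scale is reported as the geometric mean of
the two kernel widths of that maximising pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .errors import DegenerateInputError, DimensionError
from .stack_io import ImageStack

#: default kernel widths in pixels: half-octave (ratio sqrt(2)) ladder
DEFAULT_SCALES: tuple[float, ...] = (1.0, math.sqrt(2), 2.0, 2 * math.sqrt(2), 4.0,
                                     4 * math.sqrt(2), 8.0, 8 * math.sqrt(2), 16.0)

MAX_PEAKS = 200
MIN_SEPARATION_PX = 5.0


@dataclass
class ScaleSpaceResult:
    """Collapsed DOG scale space of one stack."""

    scales: tuple[float, ...]
    dog_max_projection: np.ndarray   # (z, y, x) max over adjacent-scale differences
    characteristic_scale: float      # blob width estimate in pixels
    stack: ImageStack

    def __post_init__(self) -> None:
        if not all(b > a for a, b in zip(self.scales, self.scales[1:])):
            raise ValueError("scales must be strictly increasing")
        if not (self.scales[0] <= self.characteristic_scale <= self.scales[-1]):
            raise ValueError("characteristic scale outside the scale range")


@dataclass(frozen=True)
class FeaturePeak:
    """A detected 3D local maximum of the collapsed DOG volume."""

    z: int
    y: int
    x: int
    response: float
    above_threshold: bool = True


def _blur(data: np.ndarray, sigma: float) -> np.ndarray:
    # periodic boundaries keep the total intensity of each copy identical to
    # the input (energy conservation); border peaks are discarded downstream
    return ndimage.gaussian_filter(data, sigma=sigma, mode="wrap")


def build_scale_space(stack: ImageStack, scales: Sequence[float] = DEFAULT_SCALES) -> ScaleSpaceResult:
    """Compute the max-projected DOG volume and the characteristic feature size."""
    scales = tuple(float(s) for s in scales)
    data = stack.data
    support = int(math.ceil(4 * scales[-1]))
    if min(data.shape) < 3 or min(data.shape[1:]) <= support // 4:
        raise DimensionError(
            f"stack shape {data.shape} too small for largest kernel width {scales[-1]}"
        )
    dog_max: Optional[np.ndarray] = None
    best_value = -np.inf
    best_pair = (scales[0], scales[1])
    prev = _blur(data, scales[0])
    for s0, s1 in zip(scales, scales[1:]):
        nxt = _blur(data, s1)
        dog = prev - nxt
        peak = float(dog.max())
        if peak > best_value:
            best_value = peak
            best_pair = (s0, s1)
        dog_max = dog if dog_max is None else np.maximum(dog_max, dog)
        prev = nxt
    characteristic = math.sqrt(best_pair[0] * best_pair[1])
    return ScaleSpaceResult(
        scales=scales,
        dog_max_projection=dog_max,
        characteristic_scale=characteristic,
        stack=stack,
    )


def li_threshold(values, tolerance: Optional[float] = None) -> float:
    """Cross-entropy-minimising threshold (Li's method).

    Iterates the fixed point ``t <- (mu_below - mu_above) / (ln mu_below -
    ln mu_above)`` on the class means of the values below/above ``t`` until the
    update is smaller than ``tolerance`` (default: 1e-6 of the value range).
    Values must be non-negative; zeros are lifted to a tiny positive epsilon so
    the log-means are defined.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size < 2:
        raise DegenerateInputError("need at least two values")
    vmin, vmax = float(values.min()), float(values.max())
    if vmin < 0:
        raise DegenerateInputError("Li threshold requires non-negative values")
    if vmax == vmin:
        raise DegenerateInputError("all values identical; no threshold exists")
    eps = 1e-9 * vmax
    values = np.maximum(values, eps)
    if tolerance is None:
        tolerance = 1e-6 * (vmax - vmin)

    t = float(values.mean())
    for _ in range(200):
        below = values[values <= t]
        above = values[values > t]
        if below.size == 0 or above.size == 0:
            break
        mu_b = float(below.mean())
        mu_a = float(above.mean())
        if mu_b == mu_a:
            break
        t_new = (mu_b - mu_a) / (math.log(mu_b) - math.log(mu_a))
        if abs(t_new - t) < tolerance:
            t = t_new
            break
        t = t_new
    return t


def find_peaks(ss: ScaleSpaceResult, max_peaks: int = MAX_PEAKS) -> list[FeaturePeak]:
    """3D local maxima of the collapsed DOG volume above its Li threshold.

    A voxel is a peak when it equals the maximum over its 26-neighbourhood; a
    plateau of equal values contributes its first voxel in (z, y, x) scan
    order.  Peaks are sorted by descending response (scan order breaking ties)
    and truncated to the ``max_peaks`` strongest.
    """
    dog = ss.dog_max_projection
    pos = np.clip(dog, 0.0, None)
    try:
        thr = li_threshold(pos)
    except DegenerateInputError:
        return []
    local_max = ndimage.maximum_filter(dog, size=3, mode="constant", cval=-np.inf)
    candidate = (dog >= local_max) & (dog > thr)
    if not candidate.any():
        return []
    # deterministic plateau handling: one voxel (first in scan order) per
    # connected candidate component
    labels, _ = ndimage.label(candidate, structure=np.ones((3, 3, 3), dtype=bool))
    peaks: list[FeaturePeak] = []
    coords = np.argwhere(candidate)
    seen: set[int] = set()
    for z, y, x in coords:  # argwhere returns scan order
        lab = int(labels[z, y, x])
        if lab in seen:
            continue
        seen.add(lab)
        peaks.append(FeaturePeak(int(z), int(y), int(x), float(dog[z, y, x])))
    peaks.sort(key=lambda p: (-p.response, p.z, p.y, p.x))
    return peaks[:max_peaks]


def exclude_close_peaks(
    peaks: Sequence[FeaturePeak], min_separation: float = MIN_SEPARATION_PX
) -> list[FeaturePeak]:
    """Drop every peak involved in a lateral near-coincidence.

    Two peaks whose (y, x) Euclidean distance is below ``min_separation``
    pixels are both removed — their fitting regions would overlap, so neither
    can be measured reliably.
    """
    peaks = list(peaks)
    n = len(peaks)
    bad = [False] * n
    for i in range(n):
        for j in range(i + 1, n):
            dy = peaks[i].y - peaks[j].y
            dx = peaks[i].x - peaks[j].x
            if math.hypot(dy, dx) < min_separation:
                bad[i] = bad[j] = True
    return [p for p, b in zip(peaks, bad) if not b]
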