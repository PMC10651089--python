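"""TIFF z-stack input/output with voxel calibration.

Reads single-channel 3D stacks (axis order normalised to ``(z, y, x)``) and
extracts voxel sizes from ImageJ-style TIFF metadata (X/Y resolution tags plus
the ImageJ ``spacing`` field).  Only the metric units micrometre and nanometre
are interpreted; anything else leaves the calibration absent rather than
guessing.  Calibration values are carried in nanometres throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import tifffile

from .errors import CalibrationError, DimensionError, FormatError

MIN_PLANES = 3
MIN_LATERAL = 16

# recognised length units, as nm per unit
_UNIT_NM = {
    "nm": 1.0,
    "nanometer": 1.0,
    "nanometre": 1.0,
    "um": 1000.0,
    "µm": 1000.0,  # µm
    "μm": 1000.0,  # μm (Greek mu)
    "micron": 1000.0,
    "micrometer": 1000.0,
    "micrometre": 1000.0,
}

# axis labels accepted as the z (plane) axis of a 3D series
_Z_LIKE = {"Z", "Q", "I"}


@dataclass(frozen=True)
class VoxelCalibration:
    """Physical voxel sizes in nanometres; ``None`` marks an absent value."""

    dx: Optional[float] = None
    dy: Optional[float] = None
    dz: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("dx", "dy", "dz"):
            v = getattr(self, name)
            if v is not None and not (np.isfinite(v) and v > 0):
                raise CalibrationError(f"{name} must be a positive finite size, got {v!r}")

    @property
    def lateral_complete(self) -> bool:
        return self.dx is not None and self.dy is not None

    @property
    def complete(self) -> bool:
        return self.lateral_complete and self.dz is not None


@dataclass
class ImageStack:
    """A single-channel 3D intensity volume indexed ``(z, y, x)``."""

    data: np.ndarray
    calibration: VoxelCalibration = field(default_factory=VoxelCalibration)
    source_name: str = ""
    channel_index: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise DimensionError(f"expected a 3D (z, y, x) array, got ndim={self.data.ndim}")
        nz, ny, nx = self.data.shape
        if nz < MIN_PLANES or ny < MIN_LATERAL or nx < MIN_LATERAL:
            raise DimensionError(
                f"stack {self.data.shape} below minimum size "
                f"({MIN_PLANES} planes, {MIN_LATERAL}x{MIN_LATERAL} pixels)"
            )
        if not np.all(np.isfinite(self.data)):
            raise DimensionError("stack contains non-finite intensities")
        if self.channel_index < 0:
            raise DimensionError("channel_index must be >= 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def with_calibration(self, calibration: VoxelCalibration) -> "ImageStack":
        return ImageStack(self.data, calibration, self.source_name, self.channel_index)


def _resolution_to_nm(tag_value, nm_per_unit: float) -> Optional[float]:
    """Convert an X/YResolution rational (pixels per unit) to a pixel size in nm."""
    if tag_value is None:
        return None
    try:
        num, den = tag_value
    except TypeError:
        num, den = tag_value, 1
    if num == 0:
        return None
    return float(den) / float(num) * nm_per_unit


def _read_calibration(tif: tifffile.TiffFile) -> VoxelCalibration:
    meta = tif.imagej_metadata
    if meta is None and tif.shaped_metadata:
        meta = tif.shaped_metadata[0]
    meta = meta or {}
    unit = meta.get("unit")
    if unit is None:
        return VoxelCalibration()
    nm_per_unit = _UNIT_NM.get(str(unit).strip().lower())
    if nm_per_unit is None:
        return VoxelCalibration()
    page = tif.pages[0]
    xres = page.tags.get("XResolution")
    yres = page.tags.get("YResolution")
    dx = _resolution_to_nm(xres.value if xres else None, nm_per_unit)
    dy = _resolution_to_nm(yres.value if yres else None, nm_per_unit)
    spacing = meta.get("spacing")
    dz = float(spacing) * nm_per_unit if spacing else None
    return VoxelCalibration(dx=dx, dy=dy, dz=dz)


def read_stack(path, channel_override: Optional[int] = None) -> ImageStack:
    """Read a TIFF z-stack and normalise it to ``(z, y, x)``.

    For multi-channel files the lowest channel index is returned unless
    ``channel_override`` selects another.  Voxel calibration is populated from
    ImageJ-style metadata when present, otherwise left absent.
    """
    path = Path(path)
    try:
        tif = tifffile.TiffFile(path)
    except (OSError, tifffile.TiffFileError, ValueError) as exc:
        raise FormatError(f"cannot read TIFF file {path}: {exc}") from exc
    with tif:
        series = tif.series[0]
        axes = series.axes.upper()
        data = series.asarray()
        calibration = _read_calibration(tif)

    # drop singleton time/sample axes
    for label in ("T", "S"):
        if label in axes:
            pos = axes.index(label)
            if data.shape[pos] != 1:
                raise FormatError(f"unsupported non-singleton {label} axis in {path}")
            data = np.take(data, 0, axis=pos)
            axes = axes.replace(label, "", 1)

    channel = 0 if channel_override is None else int(channel_override)
    if "C" in axes:
        pos = axes.index("C")
        if channel >= data.shape[pos]:
            raise FormatError(f"channel {channel} out of range for {data.shape[pos]} channels")
        data = np.take(data, channel, axis=pos)
        axes = axes.replace("C", "", 1)
    elif channel_override not in (None, 0):
        raise FormatError("channel_override given but file has a single channel")

    if data.ndim == 2:
        raise DimensionError(f"{path} is a single plane; a z-stack is required")
    if data.ndim != 3:
        raise FormatError(f"cannot interpret axes {series.axes!r} of {path} as a z-stack")
    if len(axes) == 3:
        if axes[1:] != "YX" or axes[0] not in _Z_LIKE:
            raise FormatError(f"ambiguous axis order {axes!r} in {path}")

    return ImageStack(
        data=np.ascontiguousarray(data, dtype=np.float64),
        calibration=calibration,
        source_name=path.name,
        channel_index=channel,
    )


def write_stack(stack: ImageStack, path) -> Path:
    """Write a stack as an ImageJ-style TIFF encoding dx/dy/dz so that
    :func:`read_stack` round-trips the calibration."""
    path = Path(path)
    cal = stack.calibration
    kwargs: dict = {}
    metadata: dict = {"axes": "ZYX"}
    if cal.dx is not None or cal.dy is not None or cal.dz is not None:
        metadata["unit"] = "um"
        # pixels per micrometre; a zero rational marks an absent lateral size
        kwargs["resolution"] = (
            1000.0 / cal.dx if cal.dx is not None else 0.0,
            1000.0 / cal.dy if cal.dy is not None else 0.0,
        )
        if cal.dz is not None:
            metadata["spacing"] = cal.dz / 1000.0
    try:
        tifffile.imwrite(path, stack.data, metadata=metadata, **kwargs)
    except OSError as exc:
        raise FormatError(f"cannot write TIFF file {path}: {exc}") from exc
    return path
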