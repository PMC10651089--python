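"""Synthetic 3D Gaussian PSF datasets with Poisson noise.

The generator emulates image stacks of a sub-resolution emitter: a 3D Gaussian
spot of lateral FWHM 273 nm and axial FWHM 1036 nm (the theoretical PSF of a
1.15 NA water-immersion lens at 515 nm emission) on a constant background of
B = 100 counts, sampled on voxel grids with lateral pixel sizes from 10 to
160 nm.  Shot noise is modelled by replacing each voxel with a Poisson draw
whose mean (and variance) is the noise-free value.  The default factorial
sweep crosses four pixel sizes with eight peak amplitudes spanning
signal-to-background ratios (SBR = (A+B)/B) from 1.5 to 11 — 32 datasets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, PlacementError
from .fitting import FWHM_FACTOR
from .stack_io import ImageStack, VoxelCalibration, write_stack

DEFAULT_FWHM_XY_NM = 273.0
DEFAULT_FWHM_Z_NM = 1036.0
DEFAULT_BACKGROUND = 100.0
DEFAULT_DZ_NM = 100.0
DEFAULT_PIXEL_SIZES_NM = (10.0, 40.0, 80.0, 160.0)
DEFAULT_AMPLITUDES = (50.0, 100.0, 150.0, 200.0, 300.0, 500.0, 750.0, 1000.0)


def sbr(A: float, B: float) -> float:
    """Signal-to-background ratio (A + B) / B."""
    if B <= 0:
        raise DomainError("background B must be positive")
    if A < 0:
        raise DomainError("amplitude A must be non-negative")
    return (A + B) / B


@dataclass(frozen=True)
class SyntheticSpec:
    """Full parameterisation of one synthetic PSF dataset."""

    A: float = 1000.0
    B: float = DEFAULT_BACKGROUND
    fwhm_xy: float = DEFAULT_FWHM_XY_NM
    fwhm_z: float = DEFAULT_FWHM_Z_NM
    dx: float = 40.0
    dz: float = DEFAULT_DZ_NM
    shape: Optional[tuple[int, int, int]] = None  # (z, y, x); None = auto
    n_spots: int = 1
    seed: Optional[int] = None  # None = noise-free

    def __post_init__(self) -> None:
        if self.A < 0 or self.B < 0:
            raise DomainError("A must be >= 0 and B >= 0")
        if self.fwhm_xy <= 0 or self.fwhm_z <= 0 or self.dx <= 0 or self.dz <= 0:
            raise DomainError("sizes must be positive")

    @property
    def sigma_xy_px(self) -> float:
        return self.fwhm_xy / FWHM_FACTOR / self.dx

    @property
    def sigma_z_px(self) -> float:
        return self.fwhm_z / FWHM_FACTOR / self.dz

    @property
    def sbr(self) -> float:
        return sbr(self.A, self.B)

    def auto_shape(self) -> tuple[int, int, int]:
        """Odd-sized volume comfortably containing the 3-sigma spot support
        plus the detector's fitting margin (tiled for multi-spot grids)."""
        half_xy = int(math.ceil(3 * self.sigma_xy_px)) + 12
        half_z = int(math.ceil(3 * self.sigma_z_px)) + 4
        lateral = max(2 * half_xy + 1, 33)
        if self.n_spots > 1:
            k = int(math.ceil(math.sqrt(self.n_spots)))
            lateral *= k
        return (2 * half_z + 1, lateral, lateral)

    def grid_centers(self, shape: tuple[int, int, int]) -> list[tuple[float, float, float]]:
        """(z, y, x) spot positions: centre voxel for one spot, else a square
        lateral grid at the central plane."""
        nz, ny, nx = shape
        cz = (nz - 1) / 2.0
        if self.n_spots <= 1:
            return [(cz, (ny - 1) / 2.0, (nx - 1) / 2.0)]
        k = int(math.ceil(math.sqrt(self.n_spots)))
        margin = max(3 * self.sigma_xy_px + 1, 10.0)
        ys = np.linspace(margin, ny - 1 - margin, k)
        xs = np.linspace(margin, nx - 1 - margin, k)
        return [(cz, float(y), float(x)) for y in ys for x in xs][: self.n_spots]


def render_noise_free(
    spec: SyntheticSpec, centers: Optional[Sequence[tuple[float, float, float]]] = None
) -> ImageStack:
    """Evaluate the 3D Gaussian spot model on the voxel grid.

    ``centers`` is an optional list of (z, y, x) spot positions in voxel
    coordinates; by default a single spot sits at the centre voxel.  Raises
    :class:`PlacementError` when a spot's 3-sigma support leaves the volume.
    """
    shape = spec.shape or spec.auto_shape()
    nz, ny, nx = shape
    if centers is None:
        centers = spec.grid_centers(shape)
    sx = spec.sigma_xy_px
    sz = spec.sigma_z_px
    for cz, cy, cx in centers:
        if (cz < 3 * sz or cz > nz - 1 - 3 * sz
                or cy < 3 * sx or cy > ny - 1 - 3 * sx
                or cx < 3 * sx or cx > nx - 1 - 3 * sx):
            raise PlacementError(
                f"spot at ({cz}, {cy}, {cx}) closer than 3 sigma to the border of {shape}"
            )
    data = np.full(shape, float(spec.B))
    zz = np.arange(nz, dtype=float)
    yy = np.arange(ny, dtype=float)
    xx = np.arange(nx, dtype=float)
    for cz, cy, cx in centers:
        gz = np.exp(-((zz - cz) ** 2) / (2 * sz * sz))
        gy = np.exp(-((yy - cy) ** 2) / (2 * sx * sx))
        gx = np.exp(-((xx - cx) ** 2) / (2 * sx * sx))
        data += spec.A * gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
    return ImageStack(
        data=data,
        calibration=VoxelCalibration(dx=spec.dx, dy=spec.dx, dz=spec.dz),
        source_name=f"synthetic_A{spec.A:g}_dx{spec.dx:g}",
    )


def apply_poisson_noise(stack: ImageStack, seed: int) -> ImageStack:
    """Replace every voxel by a Poisson draw with that voxel's value as mean."""
    if np.any(stack.data < 0):
        raise DomainError("Poisson noise requires non-negative intensities")
    rng = np.random.default_rng(seed)
    noisy = rng.poisson(stack.data).astype(np.float64)
    return ImageStack(noisy, stack.calibration, stack.source_name, stack.channel_index)


def render(spec: SyntheticSpec, centers=None) -> ImageStack:
    """Noise-free render, plus Poisson noise when the spec carries a seed."""
    stack = render_noise_free(spec, centers)
    if spec.seed is not None:
        stack = apply_poisson_noise(stack, spec.seed)
    return stack


def generate_sweep(
    output_dir,
    base_seed: int = 0,
    pixel_sizes: Sequence[float] = DEFAULT_PIXEL_SIZES_NM,
    amplitudes: Sequence[float] = DEFAULT_AMPLITUDES,
    dz: float = DEFAULT_DZ_NM,
) -> pd.DataFrame:
    """Write the factorial pixel-size x amplitude sweep of noisy datasets.

    One TIFF per (dx, A) combination plus a ``manifest.csv`` recording the
    full parameterisation and per-dataset seed.  Deterministic for a given
    ``base_seed``.
    """
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    seed_rng = np.random.default_rng(base_seed)
    rows = []
    for dx in pixel_sizes:
        for A in amplitudes:
            seed = int(seed_rng.integers(0, 2**31))
            spec = SyntheticSpec(A=float(A), dx=float(dx), dz=float(dz), seed=seed)
            stack = render(spec)
            name = f"psf_dx{dx:g}nm_A{A:g}.tif"
            write_stack(stack, output_dir / name)
            rows.append({
                "filename": name,
                "A": float(A),
                "B": spec.B,
                "SBR": spec.sbr,
                "dx": float(dx),
                "dz": float(dz),
                "fwhm_xy": spec.fwhm_xy,
                "fwhm_z": spec.fwhm_z,
                "seed": seed,
            })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(output_dir / "manifest.csv", index=False)
    return manifest
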