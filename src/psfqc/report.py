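"""End-to-end analysis workflow and report emission.

``analyze`` runs the whole pipeline on one stack — detection, proximity
exclusion, Gaussian fitting, unit conversion and field summary — and returns a
:class:`ReportBundle` mirroring the content of the printed QC report: a
metadata echo (with explicit "NA" for anything the file did not provide), the
maximum-intensity projection with numbered feature positions, the averages
table and the per-feature table.  ``export_csv`` writes the averages and
per-feature tables as CSV.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import detection
from .fitting import FieldSummary, measure_feature, summarize_field
from .stack_io import ImageStack, VoxelCalibration, read_stack

NA = "NA"


@dataclass
class ReportBundle:
    """Everything the QC report presents for one analysed stack."""

    source_name: str
    timestamp: str                       # ISO-8601 UTC; excluded from determinism
    calibration: VoxelCalibration
    units: str                           # "nm" when laterally calibrated, else "px"
    characteristic_scale_px: float
    mip: np.ndarray                      # lateral maximum-intensity projection
    overlay: list[tuple[int, float, float]]   # (feature number, x, y) in px
    summary: FieldSummary
    warnings: list[str] = field(default_factory=list)

    @property
    def n_features(self) -> int:
        return self.summary.count

    def metadata_echo(self) -> dict:
        """File metadata block with explicit NA markers."""
        cal = self.calibration
        fmt = lambda v: f"{v:g}" if v is not None else NA
        return {
            "file": self.source_name,
            "timestamp": self.timestamp,
            "pixel_size_x_nm": fmt(cal.dx),
            "pixel_size_y_nm": fmt(cal.dy),
            "z_step_nm": fmt(cal.dz),
            "units": self.units,
            "features": str(self.n_features),
        }


def _merge_calibration(
    from_file: VoxelCalibration,
    pixel_xy: Optional[float],
    pixel_z: Optional[float],
) -> VoxelCalibration:
    """Explicit overrides beat file metadata."""
    return VoxelCalibration(
        dx=pixel_xy if pixel_xy is not None else from_file.dx,
        dy=pixel_xy if pixel_xy is not None else from_file.dy,
        dz=pixel_z if pixel_z is not None else from_file.dz,
    )


def analyze_stack(stack: ImageStack) -> ReportBundle:
    """Run detection + fitting + summary on an in-memory stack."""
    warnings: list[str] = []
    ss = detection.build_scale_space(stack)
    peaks = detection.find_peaks(ss)
    peaks = detection.exclude_close_peaks(peaks)
    # fitting window scales with the detected feature size but never shrinks
    # below the five-pixel disc
    radius = max(5, int(math.ceil(2.5 * ss.characteristic_scale)))
    measurements = [
        measure_feature(stack, p, ss.characteristic_scale, radius) for p in peaks
    ]
    measurements = [m for m in measurements if m.status != "edge_rejected"]
    summary = summarize_field(measurements, shape_yx=stack.shape[1:])
    if summary.count == 0:
        warnings.append("no features detected; empty report")
    overlay = [
        (i, float(m.peak.x), float(m.peak.y)) for i, m in enumerate(measurements)
    ]
    units = "nm" if stack.calibration.lateral_complete else "px"
    return ReportBundle(
        source_name=stack.source_name,
        timestamp=_dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds"),
        calibration=stack.calibration,
        units=units,
        characteristic_scale_px=ss.characteristic_scale,
        mip=stack.data.max(axis=0),
        overlay=overlay,
        summary=summary,
        warnings=warnings,
    )


def analyze(
    path,
    pixel_xy: Optional[float] = None,
    pixel_z: Optional[float] = None,
    channel: Optional[int] = None,
) -> ReportBundle:
    """Read a TIFF stack and analyse it.

    ``pixel_xy`` / ``pixel_z`` (nm) override whatever calibration the file
    metadata carries; ``channel`` overrides the default first-channel rule.
    """
    stack = read_stack(path, channel_override=channel)
    cal = _merge_calibration(stack.calibration, pixel_xy, pixel_z)
    return analyze_stack(stack.with_calibration(cal))


_AVG_PARAMS = ("fwhm_max", "fwhm_min", "fwhm_x", "fwhm_y", "fwhm_z")


def averages_table(bundle: ReportBundle) -> pd.DataFrame:
    """Across-field averages, one row per parameter."""
    s = bundle.summary
    rows = []
    for p in _AVG_PARAMS:
        rows.append({
            "parameter": p,
            "mean_nm": s.means_nm[p],
            "sd_nm": s.stds_nm[p],
            "mean_px": s.means_px[p],
            "sd_px": s.stds_px[p],
            "n": s.count,
        })
    rows.append({
        "parameter": "r_squared_xy", "mean_nm": None, "sd_nm": None,
        "mean_px": s.mean_r2_xy, "sd_px": None, "n": s.count,
    })
    rows.append({
        "parameter": "r_squared_z", "mean_nm": None, "sd_nm": None,
        "mean_px": s.mean_r2_z, "sd_px": None, "n": s.count,
    })
    return pd.DataFrame(rows, columns=["parameter", "mean_nm", "sd_nm", "mean_px", "sd_px", "n"])


def export_csv(bundle: ReportBundle, out_dir) -> tuple[Path, Path]:
    """Write the averages and per-feature CSVs; returns their paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    avg_path = out_dir / "psf_averages.csv"
    feat_path = out_dir / "psf_features.csv"
    averages_table(bundle).to_csv(avg_path, index=False, na_rep=NA)
    bundle.summary.table.to_csv(feat_path, index=False, na_rep=NA)
    return avg_path, feat_path


def export_report_json(bundle: ReportBundle, path) -> Path:
    """Structured text summary standing in for the printed report page."""
    import json

    s = bundle.summary
    doc = {
        "metadata": bundle.metadata_echo(),
        "characteristic_scale_px": bundle.characteristic_scale_px,
        "n_features": s.count,
        "n_failed": s.n_failed,
        "averages_nm": {k: v for k, v in s.means_nm.items() if v is not None},
        "averages_px": s.means_px,
        "sd_nm": {k: v for k, v in s.stds_nm.items() if v is not None},
        "mean_r_squared_xy": s.mean_r2_xy,
        "mean_r_squared_z": s.mean_r2_z,
        "overlay": bundle.overlay,
        "warnings": bundle.warnings,
    }
    path = Path(path)
    path.write_text(json.dumps(doc, indent=2, default=float))
    return path
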