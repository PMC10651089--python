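"""Percentage RMSE scoring of FWHM estimates against synthetic ground truth.

The lateral score is the root mean square of the x- and y-axis FWHM errors as
a percentage of the true lateral width; the axial score is the absolute
percentage error of the axial FWHM.  Both are capped at 100 %, and a failed
analysis (no value returned) scores the default 100 %.  Scores are classified
into the five bands <10, 10-20, 20-30, 30-40 and >40 % for grid rendering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional

import pandas as pd

from .errors import DomainError

RMSE_CAP = 100.0
BANDS = ("<10%", "10-20%", "20-30%", "30-40%", ">40%")


def lateral_rmse_pct(X_E: float, Y_E: float, W_XY: float) -> float:
    """100 * sqrt(((X_E - W)^2 + (Y_E - W)^2) / 2) / W, capped at 100."""
    if X_E <= 0 or Y_E <= 0 or W_XY <= 0:
        raise DomainError("FWHM values must be positive")
    rmse = math.sqrt(((X_E - W_XY) ** 2 + (Y_E - W_XY) ** 2) / 2.0) / W_XY * 100.0
    return min(rmse, RMSE_CAP)


def axial_rmse_pct(Z_E: float, W_Z: float) -> float:
    """100 * |Z_E - W_Z| / W_Z, capped at 100."""
    if Z_E <= 0 or W_Z <= 0:
        raise DomainError("FWHM values must be positive")
    return min(abs(Z_E - W_Z) / W_Z * 100.0, RMSE_CAP)


def band(rmse_pct: float) -> str:
    """Five-band classification of an RMSE percentage."""
    if rmse_pct < 10:
        return BANDS[0]
    if rmse_pct < 20:
        return BANDS[1]
    if rmse_pct < 30:
        return BANDS[2]
    if rmse_pct < 40:
        return BANDS[3]
    return BANDS[4]


@dataclass(frozen=True)
class BenchmarkRecord:
    """Score of one analyzer output against one synthetic dataset."""

    dataset: str
    W_XY: float
    W_Z: float
    X_E: Optional[float]
    Y_E: Optional[float]
    Z_E: Optional[float]
    lateral_rmse_pct: float
    axial_rmse_pct: float
    capped: bool
    failed: bool


def score_record(
    dataset: str,
    W_XY: float,
    W_Z: float,
    X_E: Optional[float],
    Y_E: Optional[float],
    Z_E: Optional[float],
) -> BenchmarkRecord:
    """Score one dataset; any missing estimate marks the analysis failed."""
    failed = X_E is None or Y_E is None or Z_E is None
    if failed:
        lat = ax = RMSE_CAP
    else:
        lat = lateral_rmse_pct(X_E, Y_E, W_XY)
        ax = axial_rmse_pct(Z_E, W_Z)
    capped = lat >= RMSE_CAP or ax >= RMSE_CAP
    return BenchmarkRecord(dataset, W_XY, W_Z, X_E, Y_E, Z_E, lat, ax, capped, failed)


def score_sweep(
    manifest: pd.DataFrame,
    results: Mapping[str, Optional[tuple[Optional[float], Optional[float], Optional[float]]]],
) -> pd.DataFrame:
    """Score a whole sweep.

    ``manifest`` is the generator's manifest table (one row per dataset, keyed
    by ``filename`` with true widths ``fwhm_xy``/``fwhm_z``); ``results`` maps
    dataset filename to the estimated ``(X_E, Y_E, Z_E)`` in nm, or ``None``
    when the analysis produced nothing.  Datasets absent from ``results`` are
    scored as failed; result keys not present in the manifest are an error.
    """
    known = set(manifest["filename"])
    unknown = set(results) - known
    if unknown:
        raise DomainError(f"results for unknown datasets: {sorted(unknown)}")
    rows = []
    for rec in manifest.to_dict("records"):
        name = rec["filename"]
        est = results.get(name)
        X_E, Y_E, Z_E = est if est is not None else (None, None, None)
        scored = score_record(name, rec["fwhm_xy"], rec["fwhm_z"], X_E, Y_E, Z_E)
        row = dict(rec)
        row.update(
            X_E=X_E, Y_E=Y_E, Z_E=Z_E,
            lateral_rmse_pct=scored.lateral_rmse_pct,
            axial_rmse_pct=scored.axial_rmse_pct,
            band_lateral=band(scored.lateral_rmse_pct),
            band_axial=band(scored.axial_rmse_pct),
            capped=scored.capped,
            failed=scored.failed,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def banded_grid(scores: pd.DataFrame, value: str = "lateral_rmse_pct") -> pd.DataFrame:
    """Pivot the scores into the pixel-size x SBR grid of RMSE values."""
    return scores.pivot_table(index="dx", columns="SBR", values=value, aggfunc="first")
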