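"""Dose-volume-histogram predictors: mean lung dose and V5/V10/V20.

MLD is reported in cGy (clinical convention for lung dose tables) while dose
grids are ingested in Gy; Vx is the percentage of lung-mask voxels receiving
at least x Gy (inclusive threshold).  Volume is measured by voxel count,
which assumes uniform spacing within a grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from fractolung.errors import ConfigurationError, GeometryError, VolumeReadError
from fractolung.io import BinaryMask3D, Spacing, _check_spacing

logger = logging.getLogger(__name__)

VX_THRESHOLDS_GY = (5.0, 10.0, 20.0)


@dataclass
class DoseGrid:
    """3D absorbed-dose grid in Gy, co-registered with a lung mask."""

    dose: np.ndarray
    spacing: Spacing

    def __post_init__(self) -> None:
        self.dose = np.asarray(self.dose, dtype=float)
        if self.dose.ndim != 3:
            raise GeometryError(f"dose grid must be 3D, got {self.dose.shape}")
        if not np.all(np.isfinite(self.dose)) or np.any(self.dose < 0):
            raise ConfigurationError("dose must be finite and non-negative")
        self.spacing = _check_spacing(self.spacing)


@dataclass
class DVHMetrics:
    """MLD (cGy) and V5/V10/V20 (percent lung volume at >= 5/10/20 Gy)."""

    mld_cgy: float
    v5_pct: float
    v10_pct: float
    v20_pct: float

    def __post_init__(self) -> None:
        if self.mld_cgy < 0:
            raise ConfigurationError(f"MLD must be >= 0, got {self.mld_cgy}")
        for name in ("v5_pct", "v10_pct", "v20_pct"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ConfigurationError(
                    f"{name} = {v} is outside the physical range [0, 100]"
                )
        if not self.v5_pct >= self.v10_pct >= self.v20_pct:
            logger.warning(
                "Vx monotonicity violated (V5=%.2f, V10=%.2f, V20=%.2f); "
                "possible rounding in the source table",
                self.v5_pct, self.v10_pct, self.v20_pct,
            )

    def as_row(self) -> dict:
        return {
            "mld_cgy": self.mld_cgy,
            "v5_pct": self.v5_pct,
            "v10_pct": self.v10_pct,
            "v20_pct": self.v20_pct,
        }


def dvh_metrics(dose: DoseGrid, lung: BinaryMask3D) -> DVHMetrics:
    """Compute MLD and V5/V10/V20 over the lung mask.

    Vx = 100 * (# lung voxels with dose >= x Gy) / (# lung voxels);
    MLD = mean lung dose in Gy * 100 (cGy).
    """
    if dose.dose.shape != lung.shape:
        raise GeometryError(
            f"dose shape {dose.dose.shape} does not match lung {lung.shape}"
        )
    if lung.n_occupied == 0:
        raise ConfigurationError("lung mask is empty; DVH metrics undefined")
    d = dose.dose[lung.occupancy]
    n = d.size
    v5, v10, v20 = (100.0 * float((d >= t).sum()) / n for t in VX_THRESHOLDS_GY)
    return DVHMetrics(
        mld_cgy=float(d.mean()) * 100.0, v5_pct=v5, v10_pct=v10, v20_pct=v20
    )


REQUIRED_DVH_COLUMNS = ("patient_id", "mld_cgy", "v5_pct", "v10_pct", "v20_pct")


def read_dvh_table(path) -> pd.DataFrame:
    """Read a planning-system DVH export (CSV).

    Required columns: patient_id, mld_cgy, v5_pct, v10_pct, v20_pct.  Rows
    violating V5 >= V10 >= V20 are kept with a warning (rounding in exported
    plans can produce small violations); values outside [0, 100] percent or
    negative MLD are invalid and rejected.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise VolumeReadError(f"DVH table {path} is empty") from exc
    if df.empty:
        raise VolumeReadError(f"DVH table {path} has no rows")
    missing = [c for c in REQUIRED_DVH_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"DVH table missing mandatory columns: {missing}")
    for col in ("v5_pct", "v10_pct", "v20_pct"):
        bad = df[(df[col] < 0) | (df[col] > 100)]
        if not bad.empty:
            raise ConfigurationError(
                f"{col} outside [0, 100] for patients "
                f"{bad['patient_id'].tolist()}: physically impossible"
            )
    if (df["mld_cgy"] < 0).any():
        raise ConfigurationError("negative MLD values in DVH table")
    viol = df[~(
        (df["v5_pct"] >= df["v10_pct"]) & (df["v10_pct"] >= df["v20_pct"])
    )]
    if not viol.empty:
        logger.warning(
            "Vx monotonicity violated for patients %s; rows kept",
            viol["patient_id"].tolist(),
        )
    return df
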