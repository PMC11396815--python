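"""Thermal-image calibration and thermal-infrared vegetation indices.

Calibration fits an ordinary least-squares line ``reference = a * image + b``
to reference targets of known temperature (leaf and water) and applies it
pixelwise. Four water-stress indices are then built from calibrated canopy
and soil temperatures, all in deg C:

    TcD  = Tci - Tc                       canopy-air temperature difference
    NRCT = (Tci - Tcmin)/(Tcmax - Tcmin)  normalized canopy temperature
    CRTD = (Tcmax - Tcmin)/(Tcmax + Tcmin)
    SRTD = (Tsmax - Tsmin)/(Tsmax + Tsmin)

where Tc is air temperature, Tci the plot-mean canopy temperature, and the
canopy extremes Tcmax/Tcmin are taken over canopy pixels of the whole field
while the soil extremes Tsmax/Tsmin are within-plot. The relative-difference
ratios use deg C as published, so their values are unit-convention
dependent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CalibrationError, DomainError, MaskingError, UndefinedValueError

__all__ = [
    "CalibrationPoint",
    "CalibrationFit",
    "ThermalSummary",
    "calibrate_thermal",
    "field_canopy_extremes",
    "thermal_summary",
    "thermal_indices",
    "read_calibration_points",
]

TVI_NAMES = ("TcD", "NRCT", "CRTD", "SRTD")


@dataclass(frozen=True)
class CalibrationPoint:
    """One reference target: image-read vs true temperature, deg C."""

    image_temperature: float
    reference_temperature: float
    kind: str = "leaf"  # leaf | water

    def __post_init__(self) -> None:
        if not (np.isfinite(self.image_temperature)
                and np.isfinite(self.reference_temperature)):
            raise DomainError("calibration temperatures must be finite")


@dataclass(frozen=True)
class CalibrationFit:
    """Fitted line reference = a * image + b with its coefficient of determination."""

    a: float
    b: float
    r2: float

    def apply(self, raster: np.ndarray) -> np.ndarray:
        return self.a * np.asarray(raster, dtype=float) + self.b


@dataclass(frozen=True)
class ThermalSummary:
    """Per-plot calibrated temperature summary feeding the four indices."""

    plot_id: str
    t_canopy_mean: float
    t_c_max: float
    t_c_min: float
    t_s_max: float | None
    t_s_min: float | None
    air_temperature: float


def calibrate_thermal(
    raster: np.ndarray, points: Sequence[CalibrationPoint]
) -> tuple[np.ndarray, CalibrationFit]:
    """OLS-calibrate a thermal raster against reference points.

    Returns (calibrated raster, fit). At least two points with distinct
    image temperatures are required.
    """
    if len(points) < 2:
        raise CalibrationError(
            f"need at least 2 calibration points, got {len(points)}")
    x = np.array([p.image_temperature for p in points], dtype=float)
    y = np.array([p.reference_temperature for p in points], dtype=float)
    if np.ptp(x) == 0:
        raise CalibrationError("calibration points have identical image temperatures")
    res = stats.linregress(x, y)
    resid = y - (res.slope * x + res.intercept)
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 if ss_tot == 0 else 1.0 - (resid**2).sum() / ss_tot
    fit = CalibrationFit(float(res.slope), float(res.intercept), float(r2))
    return fit.apply(raster), fit


def field_canopy_extremes(
    thermals: Sequence[np.ndarray], canopy_masks: Sequence[np.ndarray]
) -> tuple[float, float]:
    """(Tcmax, Tcmin) over the canopy pixels of every plot in the field."""
    vals = [t[m] for t, m in zip(thermals, canopy_masks) if m.any()]
    if not vals:
        raise MaskingError("no canopy pixels in any plot")
    allv = np.concatenate(vals)
    return float(allv.max()), float(allv.min())


def thermal_summary(
    scene,
    canopy_mask: np.ndarray,
    soil_mask: np.ndarray | None,
    field_extremes: tuple[float, float],
    thermal: np.ndarray | None = None,
) -> ThermalSummary:
    """Summarize one plot's calibrated thermal raster.

    ``thermal`` overrides the scene's raster (e.g. after calibration). An
    empty soil mask leaves the soil extremes as None — SRTD is then recorded
    missing rather than aborting the plot.
    """
    t = np.asarray(thermal if thermal is not None else scene.thermal, dtype=float)
    if not canopy_mask.any():
        raise MaskingError(f"{scene.plot_id}: empty canopy mask")
    t_c_max, t_c_min = field_extremes
    if soil_mask is not None and soil_mask.any():
        t_s_max = float(t[soil_mask].max())
        t_s_min = float(t[soil_mask].min())
    else:
        t_s_max = t_s_min = None
    return ThermalSummary(
        plot_id=scene.plot_id,
        t_canopy_mean=float(t[canopy_mask].mean()),
        t_c_max=float(t_c_max),
        t_c_min=float(t_c_min),
        t_s_max=t_s_max,
        t_s_min=t_s_min,
        air_temperature=float(scene.air_temperature),
    )


def thermal_indices(s: ThermalSummary) -> dict[str, float]:
    """The four thermal indices for one plot; missing values are NaN.

    A zero denominator raises :class:`UndefinedValueError` for NRCT/CRTD;
    an absent soil mask just leaves SRTD as NaN.
    """
    out: dict[str, float] = {}
    out["TcD"] = s.t_canopy_mean - s.air_temperature
    span = s.t_c_max - s.t_c_min
    if span == 0:
        raise UndefinedValueError("NRCT: field canopy extremes coincide")
    out["NRCT"] = (s.t_canopy_mean - s.t_c_min) / span
    csum = s.t_c_max + s.t_c_min
    if csum == 0:
        raise UndefinedValueError("CRTD: zero denominator (Tcmax + Tcmin = 0)")
    out["CRTD"] = span / csum
    if s.t_s_max is None or s.t_s_min is None:
        out["SRTD"] = float("nan")
    else:
        ssum = s.t_s_max + s.t_s_min
        out["SRTD"] = ((s.t_s_max - s.t_s_min) / ssum if ssum != 0
                       else float("nan"))
    return out


def read_calibration_points(path) -> list[CalibrationPoint]:
    """Load calibration points from a CSV with image/reference temperature columns."""
    df = pd.read_csv(path, float_precision="round_trip")
    return [
        CalibrationPoint(row["image_temperature"], row["reference_temperature"],
                         row.get("kind", "leaf"))
        for _, row in df.iterrows()
    ]
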