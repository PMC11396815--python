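"""Canopy masking, plot reflectance extraction, and vegetation indices.

The vegetation-index (VI) catalog holds 15 indices built from the blue,
green, red, red-edge and near-infrared band reflectances (RB, RG, RR, RRE,
RNIR). Two candidate NIR bands exist (800 and 900 nm); per index, the band
whose VI correlates more strongly with the response on the training split is
kept.

Two catalog entries deliberately follow a non-canonical published form and
are kept that way for comparability: OSAVI uses the green band where the
canonical form uses red, and NLI uses the red edge. See docs/methods.md.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import MaskingError, UndefinedValueError
from .synthetic import BANDS, PlotScene

__all__ = [
    "VI_NAMES",
    "ReflectanceVector",
    "canopy_mask",
    "plot_reflectance",
    "compute_vi",
    "compute_all_vis",
    "select_nir_band",
]

VI_NAMES = ("MTVI", "SAVI", "OSAVI", "MSAVI", "DVI", "GNDVI", "GCVI", "NLI",
            "RVI", "RDVI", "MSR", "NDRE", "TVI", "NDVI", "EVI")

_BAND_INDEX = {wl: i for i, wl in enumerate(BANDS)}


@dataclass(frozen=True)
class ReflectanceVector:
    """Plot-mean reflectance per band role, plus the soil-adjustment constant X."""

    r_blue: float
    r_green: float
    r_red: float
    r_rededge: float
    r_nir800: float
    r_nir900: float
    x: float = 0.16

    def nir(self, nir_band: int) -> float:
        if nir_band == 800:
            return self.r_nir800
        if nir_band == 900:
            return self.r_nir900
        raise UndefinedValueError(f"nir_band must be 800 or 900, got {nir_band}")


def _ndvi_image(scene: PlotScene, nir_band: int = 800) -> np.ndarray:
    red = scene.reflectance[_BAND_INDEX[680]]
    nir = scene.reflectance[_BAND_INDEX[nir_band]]
    with np.errstate(divide="ignore", invalid="ignore"):
        ndvi = np.where(nir + red > 0, (nir - red) / (nir + red), 0.0)
    return ndvi


def canopy_mask(
    scene: PlotScene, vi_threshold: float = 0.3, nir_band: int = 800
) -> tuple[np.ndarray, int]:
    """Boolean canopy mask: pixels with NDVI above ``vi_threshold``.

    Returns (mask, number of masked-in pixels). Raises
    :class:`MaskingError` when no pixel passes — the plot is unusable.
    """
    mask = _ndvi_image(scene, nir_band) > vi_threshold
    count = int(mask.sum())
    if count == 0:
        raise MaskingError(
            f"{scene.plot_id}: no pixel exceeds NDVI threshold {vi_threshold}")
    return mask, count


def plot_reflectance(scene: PlotScene, mask: np.ndarray) -> ReflectanceVector:
    """Per-band arithmetic mean reflectance over masked pixels."""
    if not mask.any():
        raise MaskingError(f"{scene.plot_id}: empty mask")
    means = scene.reflectance[:, mask].mean(axis=1)
    return ReflectanceVector(
        r_blue=float(means[_BAND_INDEX[490]]),
        r_green=float(means[_BAND_INDEX[555]]),
        r_red=float(means[_BAND_INDEX[680]]),
        r_rededge=float(means[_BAND_INDEX[720]]),
        r_nir800=float(means[_BAND_INDEX[800]]),
        r_nir900=float(means[_BAND_INDEX[900]]),
    )


def compute_vi(name: str, refl: ReflectanceVector, nir_band: int = 800) -> float:
    """One vegetation index from plot-mean reflectances.

    Raises :class:`UndefinedValueError` on an exactly-zero denominator (the
    value is to be recorded as missing, never fabricated).
    """
    rb, rg, rr = refl.r_blue, refl.r_green, refl.r_red
    rre, x = refl.r_rededge, refl.x
    rnir = refl.nir(nir_band)

    def div(num: float, den: float) -> float:
        if den == 0:
            raise UndefinedValueError(f"{name}: zero denominator")
        return num / den

    if name == "MTVI":
        return 1.2 * (1.2 * (rnir - rg) - 2.5 * (rre - rg))
    if name == "SAVI":
        return 1.5 * div(rnir - rr, rnir + rr + 0.5)
    if name == "OSAVI":  # green-band form, as published
        return (1 + x) * div(rnir - rg, rnir + rg + x)
    if name == "MSAVI":
        disc = (2 * rnir + 1) ** 2 - 8 * (rnir - rr)
        if disc < 0:
            raise UndefinedValueError("MSAVI: negative discriminant")
        return (2 * rnir + 1 - np.sqrt(disc)) / 2
    if name == "DVI":
        return rnir - rr
    if name == "GNDVI":
        return div(rnir - rg, rnir + rg)
    if name == "GCVI":
        return div(rnir, rg) - 1.0
    if name == "NLI":  # red-edge form, as published
        return div(rnir**2 - rre, rnir**2 + rre)
    if name == "RVI":
        return div(rnir, rr)
    if name == "RDVI":
        if rnir + rr <= 0:
            raise UndefinedValueError("RDVI: non-positive denominator")
        return (rnir - rr) / np.sqrt(rnir + rr)
    if name == "MSR":
        ratio = div(rnir, rr)
        if ratio + 1 <= 0:
            raise UndefinedValueError("MSR: non-positive denominator")
        return (ratio - 1.0) / np.sqrt(ratio + 1.0)
    if name == "NDRE":
        return div(rnir - rre, rnir + rre)
    if name == "TVI":
        return 60.0 * (rnir - rg) - 100.0 * (rr - rg)
    if name == "NDVI":
        return div(rnir - rr, rnir + rr)
    if name == "EVI":
        return 2.5 * div(rnir - rr, rnir + 6 * rr - 7.5 * rb + 1)
    raise UndefinedValueError(f"unknown vegetation index {name!r}")


def compute_all_vis(refl: ReflectanceVector, nir_band: int = 800) -> dict[str, float]:
    """All 15 catalog indices for one NIR-band choice; missing values are NaN."""
    out: dict[str, float] = {}
    for name in VI_NAMES:
        try:
            out[name] = compute_vi(name, refl, nir_band)
        except UndefinedValueError:
            out[name] = float("nan")
    return out


def select_nir_band(
    vi_800: dict[str, np.ndarray],
    vi_900: dict[str, np.ndarray],
    smc: np.ndarray,
) -> dict[str, int]:
    """Per-index NIR band choice by larger |Pearson r| with the response.

    ``vi_800`` / ``vi_900`` map index name -> vector over (training) plots.
    Ties pick 800 nm. A constant VI vector at one band yields the other band
    with a warning; constant at both excludes the index.
    """
    smc = np.asarray(smc, dtype=float)
    choice: dict[str, int] = {}
    for name in vi_800:
        scores = {}
        for band, vec in ((800, vi_800[name]), (900, vi_900[name])):
            v = np.asarray(vec, dtype=float)
            ok = np.isfinite(v) & np.isfinite(smc)
            if ok.sum() < 3 or np.std(v[ok]) == 0 or np.std(smc[ok]) == 0:
                warnings.warn(
                    f"{name} at {band} nm: correlation undefined (constant)",
                    stacklevel=2)
                continue
            scores[band] = abs(np.corrcoef(v[ok], smc[ok])[0, 1])
        if not scores:
            warnings.warn(f"{name}: excluded, undefined at both NIR bands",
                          stacklevel=2)
            continue
        if len(scores) == 1:
            choice[name] = next(iter(scores))
        else:
            choice[name] = 800 if scores[800] >= scores[900] else 900
    return choice
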