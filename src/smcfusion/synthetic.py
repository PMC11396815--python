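"""Seeded synthetic UAV experiments for pipeline testing.

The generator emulates the data layout of a plot-trial flight campaign: 96
plots (16 treatments x 3 replicates x 2 years), each observed as a 6-band
reflectance raster (490/555/680/720/800/900 nm), a thermal raster (deg C),
and gravimetric soil moisture content (SMC) at three depth layers (0-20,
20-40, 40-60 cm).

Planted statistical structure, all linear in the 0-20 cm SMC:

* plot-mean NIR reflectance over canopy pixels increases with SMC (vigour);
* plot-mean canopy temperature decreases with SMC (transpirative cooling);
* within-canopy spatial heterogeneity decreases with SMC, so GLCM texture
  statistics carry a real SMC dependence;
* the 20-40 and 40-60 cm layers are noisier copies of the surface layer
  (Gaussian copula with the configured ``layer_correlation``), so every
  planted signal weakens with depth.

Soil-background pixels get a hot, high-red / low-NIR signature so that NDVI
masking and the soil relative-temperature difference are non-degenerate.

Plot-level residual variance (``plot_effect_sd_*``) is what sets the
plot-scale correlation between SMC and the remote-sensing features: pixel
noise alone averages out over thousands of canopy pixels. Defaults put
|r(SMC, plot-mean NIR)| near 0.65-0.7 for the surface layer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy.ndimage import gaussian_filter
from scipy.special import ndtr

from .errors import ConfigurationError, DomainError

__all__ = [
    "BANDS",
    "BAND_ROLES",
    "CouplingStrengths",
    "SceneConfig",
    "GroundTruth",
    "PlotScene",
    "generate_experiment",
    "write_experiment",
    "read_experiment",
]

#: Center wavelengths (nm), ascending; raster band order follows this tuple.
BANDS: tuple[int, ...] = (490, 555, 680, 720, 800, 900)

#: Semantic role of each band, keyed by wavelength.
BAND_ROLES = {490: "blue", 555: "green", 680: "red", 720: "rededge",
              800: "nir800", 900: "nir900"}

# Mean canopy reflectance per band for a vigorous flowering canopy, and the
# signed reflectance change across the full SMC range (wet minus dry midpoint
# slope; NIR rises with moisture, red falls slightly).
_CANOPY_BASE = {490: 0.04, 555: 0.08, 680: 0.05, 720: 0.25, 800: 0.45, 900: 0.43}
_SMC_SLOPE = {490: -0.005, 555: 0.010, 680: -0.020, 720: 0.060, 800: 0.150, 900: 0.120}

# Dry-soil background spectrum: NDVI ~= 0.15, below the 0.3 canopy threshold.
_SOIL_REFL = {490: 0.08, 555: 0.12, 680: 0.22, 720: 0.26, 800: 0.30, 900: 0.32}

_TREATMENTS = [f"{n}-{m}" for n in ("N0", "N1", "N2", "N3")
               for m in ("SM", "SFM", "FM", "NM")]

_LAYERS = ("0-20", "20-40", "40-60")

# Canopy-temperature model: air + _T_OFFSET - _T_SLOPE * s_norm (deg C).
_T_OFFSET = 4.0
_T_SLOPE = 5.0
_T_SOIL_EXCESS = 8.0       # soil runs hotter than air
_T_SPATIAL_AMP = 0.8       # within-canopy thermal patchiness, deg C
_TEXTURE_BASE = 0.12       # relative amplitude of canopy spatial structure
_TEXTURE_SMC_DECAY = 0.6   # fractional amplitude drop from driest to wettest
_TEXTURE_PLOT_SD = 0.15    # lognormal sd of per-plot amplitude residual


@dataclass(frozen=True)
class CouplingStrengths:
    """Dimensionless multipliers on the planted SMC links (1.0 = default)."""

    reflectance: float = 1.0
    temperature: float = 1.0
    texture: float = 1.0


@dataclass(frozen=True)
class SceneConfig:
    """Full description of one synthetic experiment."""

    n_plots: int = 96
    raster_size: int = 64
    bands: tuple[int, ...] = BANDS
    #: (min, max) SMC fraction per depth layer, surface first. The site is a
    #: loam with field capacity ~0.24 and wilting point ~0.085 by mass, so
    #: treatments span roughly wilting point to field capacity.
    smc_range_by_layer: tuple[tuple[float, float], ...] = (
        (0.09, 0.24), (0.10, 0.25), (0.11, 0.25))
    layer_correlation: float = 0.8
    noise_sd_reflectance: float = 0.01
    noise_sd_thermal: float = 0.3
    soil_fraction: float = 0.15
    air_temperature: float = 30.0
    coupling_strengths: CouplingStrengths = field(default_factory=CouplingStrengths)
    #: Plot-level residual sd of band reflectance, as a fraction of the band
    #: mean (shared-cause variation the planted SMC link does not explain).
    plot_effect_sd_reflectance: float = 0.10
    #: Plot-level residual sd of canopy temperature, deg C.
    plot_effect_sd_thermal: float = 1.5
    #: Optional additive SMC offset per treatment label (fraction); empty by
    #: default — treatments are labels only.
    treatment_offsets: dict = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.n_plots < 6:
            raise ConfigurationError(f"n_plots must be >= 6, got {self.n_plots}")
        if self.raster_size < 8:
            raise ConfigurationError(
                f"raster_size must be >= 8, got {self.raster_size}")
        if tuple(self.bands) != BANDS:
            raise ConfigurationError(f"bands must be {BANDS}, got {self.bands}")
        if not (0.0 <= self.soil_fraction < 1.0):
            raise ConfigurationError(
                f"soil_fraction must be in [0, 1), got {self.soil_fraction}")
        if len(self.smc_range_by_layer) != 3:
            raise ConfigurationError("smc_range_by_layer needs 3 (min, max) pairs")
        for k, (lo, hi) in enumerate(self.smc_range_by_layer):
            if not (0.0 < lo < hi < 1.0):
                raise ConfigurationError(
                    f"smc_range_by_layer[{k}] must satisfy 0 < min < max < 1, "
                    f"got ({lo}, {hi})")
        if not (0.0 <= self.layer_correlation <= 1.0):
            raise ConfigurationError(
                f"layer_correlation must be in [0, 1], got {self.layer_correlation}")
        for name in ("noise_sd_reflectance", "noise_sd_thermal",
                     "plot_effect_sd_reflectance", "plot_effect_sd_thermal"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """Measured SMC fractions for one plot, surface layer first."""

    plot_id: str
    treatment: str
    smc: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not all(0.0 < w < 1.0 for w in self.smc):
            raise DomainError(f"SMC fractions must lie in (0, 1), got {self.smc}")


@dataclass
class PlotScene:
    """Rasters for one plot: reflectance (bands, H, W), thermal (H, W)."""

    plot_id: str
    reflectance: np.ndarray
    thermal: np.ndarray
    canopy_mask: np.ndarray | None
    soil_mask: np.ndarray | None
    air_temperature: float


def _layer_smc(config: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    """(n_plots, 3) SMC fractions via a Gaussian copula across depth."""
    n = config.n_plots
    rho = config.layer_correlation
    z = np.empty((n, 3))
    z[:, 0] = rng.standard_normal(n)
    for k in (1, 2):
        z[:, k] = rho * z[:, k - 1] + np.sqrt(1.0 - rho**2) * rng.standard_normal(n)
    u = ndtr(z)  # Phi(z): uniform margins, rank correlation preserved
    smc = np.empty_like(u)
    for k, (lo, hi) in enumerate(config.smc_range_by_layer):
        smc[:, k] = lo + u[:, k] * (hi - lo)
    return smc


def generate_experiment(
    config: SceneConfig,
) -> tuple[list[PlotScene], list[GroundTruth]]:
    """Generate one seeded experiment: scenes plus matching ground truth.

    Deterministic: the same config (including seed) reproduces every array
    bit-for-bit.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, size = config.n_plots, config.raster_size
    npix = size * size
    cs = config.coupling_strengths

    smc = _layer_smc(config, rng)
    treatments = [_TREATMENTS[i % len(_TREATMENTS)] for i in range(n)]
    if config.treatment_offsets:
        offs = np.array([config.treatment_offsets.get(t, 0.0) for t in treatments])
        smc = np.clip(smc + offs[:, None], 1e-6, 1.0 - 1e-6)

    lo0, hi0 = config.smc_range_by_layer[0]
    s_norm = (smc[:, 0] - lo0) / (hi0 - lo0)

    scenes: list[PlotScene] = []
    truths: list[GroundTruth] = []
    for i in range(n):
        plot_id = f"plot{i + 1:03d}"
        # soil-background pixels are a random subset of the raster
        n_soil = int(round(config.soil_fraction * npix))
        soil_flat = rng.choice(npix, size=n_soil, replace=False)
        soil_mask = np.zeros(npix, dtype=bool)
        soil_mask[soil_flat] = True
        soil_mask = soil_mask.reshape(size, size)
        canopy_mask = ~soil_mask

        # shared canopy-structure field, zero-meaned over canopy so plot
        # means stay exactly linear in SMC
        struct = gaussian_filter(rng.standard_normal((size, size)), sigma=2.0)
        struct /= struct.std() or 1.0
        struct -= struct[canopy_mask].mean()
        amp = (_TEXTURE_BASE * cs.texture
               * (1.0 - _TEXTURE_SMC_DECAY * s_norm[i])
               * np.exp(rng.normal(0.0, _TEXTURE_PLOT_SD)))

        refl = np.empty((len(BANDS), size, size))
        for b, wl in enumerate(BANDS):
            base = (_CANOPY_BASE[wl]
                    + cs.reflectance * _SMC_SLOPE[wl] * (s_norm[i] - 0.5))
            plot_off = rng.normal(
                0.0, config.plot_effect_sd_reflectance * _CANOPY_BASE[wl])
            band = base + plot_off + _CANOPY_BASE[wl] * amp * struct
            band = np.where(canopy_mask, band, _SOIL_REFL[wl])
            if config.noise_sd_reflectance > 0:
                band = band + rng.normal(
                    0.0, config.noise_sd_reflectance, (size, size))
            refl[b] = np.clip(band, 0.0, 1.0)

        t_field = gaussian_filter(rng.standard_normal((size, size)), sigma=2.0)
        t_field /= t_field.std() or 1.0
        t_field -= t_field[canopy_mask].mean()
        t_canopy = (config.air_temperature + _T_OFFSET
                    - cs.temperature * _T_SLOPE * s_norm[i]
                    + rng.normal(0.0, config.plot_effect_sd_thermal))
        thermal = t_canopy + _T_SPATIAL_AMP * t_field
        soil_t = (config.air_temperature + _T_SOIL_EXCESS
                  + 2.0 * gaussian_filter(rng.standard_normal((size, size)), 2.0))
        thermal = np.where(canopy_mask, thermal, soil_t)
        if config.noise_sd_thermal > 0:
            thermal = thermal + rng.normal(
                0.0, config.noise_sd_thermal, (size, size))
        thermal = np.clip(thermal,
                          config.air_temperature - 25.0,
                          config.air_temperature + 25.0)

        scenes.append(PlotScene(plot_id, refl, thermal, canopy_mask, soil_mask,
                                config.air_temperature))
        truths.append(GroundTruth(plot_id, treatments[i], tuple(smc[i])))
    return scenes, truths


def truths_to_frame(truths: Sequence[GroundTruth]) -> pd.DataFrame:
    """Ground truth as a DataFrame with one smc_* column per depth layer."""
    return pd.DataFrame(
        {
            "plot_id": [t.plot_id for t in truths],
            "treatment": [t.treatment for t in truths],
            "smc_0_20": [t.smc[0] for t in truths],
            "smc_20_40": [t.smc[1] for t in truths],
            "smc_40_60": [t.smc[2] for t in truths],
        }
    )


def _calibration_points(scenes: Sequence[PlotScene]) -> pd.DataFrame:
    """Reference-temperature points (leaf and water) on the identity line."""
    rows = []
    for scene in scenes[:3]:
        t = float(scene.thermal[scene.canopy_mask].mean())
        rows.append({"image_temperature": t, "reference_temperature": t,
                     "kind": "leaf"})
    for t in (18.0, 20.0, 22.0):
        rows.append({"image_temperature": t, "reference_temperature": t,
                     "kind": "water"})
    return pd.DataFrame(rows)


def write_experiment(
    scenes: Sequence[PlotScene],
    truths: Sequence[GroundTruth],
    out_dir,
) -> dict:
    """Write an experiment to disk; returns the manifest (also saved as JSON).

    One multi-band TIFF per plot for reflectance (band order = ascending
    wavelength), one single-band TIFF for thermal, a ground-truth CSV, and a
    calibration-point CSV.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:  # pragma: no cover - filesystem dependent
        raise OSError(f"cannot create output directory {out}: {exc}") from exc

    files: list[str] = []
    for scene in scenes:
        rpath = out / f"{scene.plot_id}_reflectance.tif"
        tpath = out / f"{scene.plot_id}_thermal.tif"
        # float64 keeps ingest mode bit-identical to the in-memory path
        tifffile.imwrite(rpath, scene.reflectance.astype(np.float64),
                         photometric="minisblack")
        tifffile.imwrite(tpath, scene.thermal.astype(np.float64),
                         photometric="minisblack")
        files.extend([rpath.name, tpath.name])

    truth_path = out / "ground_truth.csv"
    # %.17g keeps the CSV round-trip float-exact
    truths_to_frame(truths).to_csv(truth_path, index=False, float_format="%.17g")
    files.append(truth_path.name)

    calib_path = out / "calibration_points.csv"
    _calibration_points(scenes).to_csv(calib_path, index=False,
                                       float_format="%.17g")
    files.append(calib_path.name)

    manifest = {
        "n_plots": len(scenes),
        "bands_nm": list(BANDS),
        "air_temperature": scenes[0].air_temperature if scenes else None,
        "files": files,
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def read_experiment(in_dir) -> tuple[list[PlotScene], list[GroundTruth]]:
    """Load an experiment written by :func:`write_experiment`.

    Masks are left unset; the pipeline recomputes them from NDVI so that
    ingest mode and in-memory mode follow the same code path.
    """
    src = Path(in_dir)
    with open(src / "manifest.json", encoding="utf-8") as fh:
        manifest = json.load(fh)
    air = manifest["air_temperature"]
    truth_df = pd.read_csv(src / "ground_truth.csv",
                           float_precision="round_trip")
    scenes, truths = [], []
    for _, row in truth_df.iterrows():
        pid = row["plot_id"]
        refl = tifffile.imread(src / f"{pid}_reflectance.tif").astype(float)
        thermal = tifffile.imread(src / f"{pid}_thermal.tif").astype(float)
        scenes.append(PlotScene(pid, refl, thermal, None, None, air))
        truths.append(GroundTruth(pid, row["treatment"],
                                  (row["smc_0_20"], row["smc_20_40"],
                                   row["smc_40_60"])))
    return scenes, truths


def with_seed(config: SceneConfig, seed: int) -> SceneConfig:
    """Copy of ``config`` with a different seed (convenience for sweeps)."""
    return replace(config, seed=seed)
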