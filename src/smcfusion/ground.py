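"""Ground-measurement arithmetic: gravimetric soil moisture and plot averaging.

Soil moisture content (SMC) is measured by oven-drying: a sample of wet mass
``M1`` (g) is dried to constant mass ``M2`` (g) and the water content is the
lost mass expressed as a fraction. The wet-basis form ``W = (M1 - M2) / M1``
is the default; the conventional dry-basis form ``(M1 - M2) / M2`` is
available via ``basis="dry"``. Five auger samples per plot are averaged into
the plot value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError

__all__ = ["SoilSample", "gravimetric_smc", "plot_mean", "read_samples", "write_plot_smc"]


@dataclass(frozen=True)
class SoilSample:
    """One oven-dried soil sample: wet mass M1 and dry mass M2, in grams."""

    wet_mass_g: float
    dry_mass_g: float

    def __post_init__(self) -> None:
        if not (self.wet_mass_g > 0):
            raise DomainError(f"wet_mass_g must be positive, got {self.wet_mass_g}")
        if not (0 < self.dry_mass_g <= self.wet_mass_g):
            raise DomainError(
                f"dry_mass_g must satisfy 0 < M2 <= M1, got M1={self.wet_mass_g}, "
                f"M2={self.dry_mass_g}"
            )


def gravimetric_smc(sample: SoilSample, basis: str = "wet") -> float:
    """Water content of one sample as a fraction.

    ``basis="wet"`` (default) returns ``(M1 - M2) / M1``; ``basis="dry"``
    returns ``(M1 - M2) / M2``.
    """
    m1, m2 = sample.wet_mass_g, sample.dry_mass_g
    if basis == "wet":
        return (m1 - m2) / m1
    if basis == "dry":
        return (m1 - m2) / m2
    raise DomainError(f"basis must be 'wet' or 'dry', got {basis!r}")


def plot_mean(values: Sequence[float] | Iterable[float]) -> float:
    """Arithmetic mean of point measurements within a plot (five-point rule)."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise DomainError("plot_mean requires at least one measurement")
    return float(arr.mean())


def read_samples(path) -> pd.DataFrame:
    """Read a per-point sample-mass CSV with columns plot_id, wet_mass_g, dry_mass_g."""
    df = pd.read_csv(path)
    required = {"plot_id", "wet_mass_g", "dry_mass_g"}
    missing = required - set(df.columns)
    if missing:
        raise DomainError(f"sample CSV missing columns: {sorted(missing)}")
    return df


def write_plot_smc(samples: pd.DataFrame, path, basis: str = "wet") -> pd.DataFrame:
    """Aggregate point samples to plot-level SMC and write a CSV.

    Returns the plot-level table (plot_id, smc).
    """
    smc = samples.apply(
        lambda row: gravimetric_smc(
            SoilSample(row["wet_mass_g"], row["dry_mass_g"]), basis=basis
        ),
        axis=1,
    )
    out = (
        samples.assign(smc=smc)
        .groupby("plot_id", sort=True)["smc"]
        .mean()
        .reset_index()
    )
    out.to_csv(path, index=False)
    return out
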