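"""Pearson-correlation significance screening of candidate features.

Each feature column is correlated with the layer's soil moisture and kept
when its two-sided p-value (t-test with n-2 degrees of freedom) is below
``alpha`` (0.01 by default). No multiple-testing correction is applied —
selection is deliberately per-feature, a known liberal choice documented in
docs/methods.md. At n = 96 the implied critical |r| is about 0.262.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError

__all__ = [
    "FAMILIES",
    "ScreeningRecord",
    "pearson_r",
    "r_pvalue",
    "critical_r",
    "screen_features",
    "screening_report",
]

FAMILIES = ("VIs", "TF", "TIs", "TVIs")


@dataclass(frozen=True)
class ScreeningRecord:
    """Screening outcome for one (feature, depth layer) pair."""

    feature_name: str
    family: str
    layer: str
    r: float
    p: float
    selected: bool


def pearson_r(x, y) -> float:
    """Sample Pearson correlation of two equal-length non-constant vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("pearson_r needs two equal-length 1-D vectors")
    if x.size < 3:
        raise DomainError("pearson_r needs at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DomainError("correlation undefined for a constant vector")
    return float(np.corrcoef(x, y)[0, 1])


def r_pvalue(r: float, n: int) -> float:
    """Two-sided p-value for a sample correlation r at sample size n.

    Uses t = r * sqrt(n-2) / sqrt(1-r^2) against Student's t with n-2 df;
    |r| = 1 maps to p = 0 by convention.
    """
    if n < 3:
        raise DomainError("r_pvalue needs n >= 3")
    if abs(r) > 1:
        raise DomainError(f"|r| must be <= 1, got {r}")
    if abs(r) == 1:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def critical_r(n: int, alpha: float = 0.01) -> float:
    """Smallest |r| significant at ``alpha`` for sample size n (two-sided)."""
    tcrit = stats.t.isf(alpha / 2.0, df=n - 2)
    return float(tcrit / np.sqrt(n - 2 + tcrit**2))


def screen_features(
    table: pd.DataFrame,
    smc_by_layer: dict[str, np.ndarray],
    families: dict[str, str],
    alpha: float = 0.01,
) -> list[ScreeningRecord]:
    """Screen every feature column against every depth layer.

    ``table`` is plots x features; ``families`` maps feature name to its
    family (VIs/TF/TIs/TVIs). Features whose correlation is undefined
    (constant or too few finite values) are excluded with a warning. Output
    is ordered by (layer, family, |r| descending) for stable reports.
    """
    records: list[ScreeningRecord] = []
    for layer, smc in smc_by_layer.items():
        y = np.asarray(smc, dtype=float)
        for name in table.columns:
            x = table[name].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 3 or np.std(x[ok]) == 0:
                warnings.warn(
                    f"{name} ({layer}): correlation undefined, excluded",
                    stacklevel=2)
                continue
            r = pearson_r(x[ok], y[ok])
            p = r_pvalue(r, int(ok.sum()))
            records.append(ScreeningRecord(
                feature_name=name,
                family=families.get(name, "?"),
                layer=layer,
                r=r,
                p=p,
                selected=bool(p < alpha),
            ))
    fam_order = {f: i for i, f in enumerate(FAMILIES)}
    records.sort(key=lambda rec: (rec.layer, fam_order.get(rec.family, 99),
                                  -abs(rec.r)))
    present = set(families.values()) & set(FAMILIES)
    for layer in smc_by_layer:
        for fam in sorted(present, key=FAMILIES.index):
            if not any(rec.selected and rec.layer == layer and rec.family == fam
                       for rec in records):
                warnings.warn(
                    f"no {fam} feature selected for layer {layer} at "
                    f"alpha={alpha}", stacklevel=2)
    return records


def screening_report(records: list[ScreeningRecord]) -> pd.DataFrame:
    """Records as a DataFrame with significance stars (* p<0.05, ** p<0.01)."""
    df = pd.DataFrame([vars(rec) for rec in records])
    if df.empty:
        return df
    df["stars"] = np.select([df["p"] < 0.01, df["p"] < 0.05], ["**", "*"], "")
    return df
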