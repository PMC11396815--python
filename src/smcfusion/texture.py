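"""Gray-level co-occurrence matrix (GLCM) textures and texture indices.

Per spectral band, the raster is quantized to ``G`` gray levels and a 3x3
sliding window computes eight GLCM statistics (mean, variance, homogeneity,
contrast, dissimilarity, entropy, second moment, correlation) at distance 1
in the four directions 0/45/90/135 degrees; the four directional values are
averaged into the final texture image, whose canopy-masked mean is the
plot's texture-feature value. With six bands this yields 48 texture
identities per plot, named like ``Mea3`` (feature Mea, band 3).

Texture indices combine two texture values T1, T2:

    NDTI = (T1-T2)/(T1+T2)      DTI  = T1-T2         RTI  = T1/T2
    NTI  = (T1^2-T2)/(T1^2+T2)  RDTI = 1/T1 - 1/T2   RATI = 1/T1 + 1/T2

and :func:`search_texture_indices` scores every ordered pair of the 48
identities (identical pairs included) against the response, keeping the pair
with maximal |Pearson r| per form.

Conventions: GLCMs use symmetric counting normalized to probabilities; gray
levels are the 0-based quantization bins; entropy is -sum P ln P with
0 ln 0 = 0; the window feature value is assigned to the center pixel and
edge pixels (no full window) are skipped. Directional offsets follow the
(row, col) = (sin a, cos a) convention, which symmetric counting makes
sign-free.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ConfigurationError, DomainError, SearchError, UndefinedValueError

__all__ = [
    "FEATURES",
    "TI_FORMS",
    "GLCMMatrix",
    "quantize_band",
    "glcm_window",
    "texture_stats",
    "texture_images",
    "band_texture_image",
    "plot_texture",
    "texture_index",
    "search_texture_indices",
    "identity_names",
]

FEATURES = ("Mea", "Var", "Hom", "Con", "Dis", "Ent", "Sec", "Cor")
TI_FORMS = ("NDTI", "DTI", "RTI", "NTI", "RDTI", "RATI")
DIRECTIONS = (0, 45, 90, 135)

#: (row, col) pixel offset per direction at distance 1.
_OFFSETS = {0: (0, 1), 45: (1, 1), 90: (1, 0), 135: (1, -1)}


@dataclass(frozen=True)
class GLCMMatrix:
    """Normalized symmetric co-occurrence matrix for one window/direction."""

    P: np.ndarray
    levels: int
    direction: int
    distance: int = 1

    def __post_init__(self) -> None:
        if self.P.shape != (self.levels, self.levels):
            raise DomainError("GLCM shape does not match gray-level count")
        if not np.isclose(self.P.sum(), 1.0, atol=1e-12):
            raise DomainError("GLCM probabilities must sum to 1")


def quantize_band(raster: np.ndarray, levels: int = 32) -> np.ndarray:
    """Linear min-max quantization of a band to integer bins [0, levels-1].

    A constant raster maps to bin 0.
    """
    if levels < 2:
        raise ConfigurationError(f"levels must be >= 2, got {levels}")
    arr = np.asarray(raster, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise DomainError("raster contains non-finite values")
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        return np.zeros(arr.shape, dtype=np.int64)
    q = np.floor((arr - lo) / (hi - lo) * levels).astype(np.int64)
    return np.clip(q, 0, levels - 1)


def glcm_window(
    q: np.ndarray, direction: int, distance: int = 1, levels: int | None = None
) -> GLCMMatrix:
    """Symmetric GLCM of one integer window at the given direction/distance."""
    q = np.asarray(q)
    if direction not in _OFFSETS:
        raise ConfigurationError(f"direction must be one of {DIRECTIONS}")
    g = int(levels if levels is not None else q.max() + 1)
    dr, dc = (o * distance for o in _OFFSETS[direction])
    h, w = q.shape
    counts = np.zeros((g, g), dtype=float)
    n_pairs = 0
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                a, b = q[r, c], q[r2, c2]
                counts[a, b] += 1
                counts[b, a] += 1
                n_pairs += 1
    if n_pairs == 0:
        raise DomainError(
            f"window {q.shape} has no pixel pairs at direction {direction}, "
            f"distance {distance}")
    return GLCMMatrix(counts / counts.sum(), g, direction, distance)


def texture_stats(m: GLCMMatrix) -> dict[str, float]:
    """The eight texture statistics of one GLCM.

    Correlation returns the sentinel 0.0 when either marginal variance is
    zero (degenerate single-level window).
    """
    P = m.P
    g = m.levels
    i = np.arange(g, dtype=float)
    pi = P.sum(axis=1)  # marginal over rows (i)
    pj = P.sum(axis=0)
    mea_i = float(i @ pi)
    mea_j = float(i @ pj)
    var_i = float(((i - mea_i) ** 2) @ pi)
    var_j = float(((i - mea_j) ** 2) @ pj)
    ii = i[:, None]
    jj = i[None, :]
    diff = ii - jj
    with np.errstate(divide="ignore", invalid="ignore"):
        logP = np.where(P > 0, np.log(np.where(P > 0, P, 1.0)), 0.0)
    if var_i > 0 and var_j > 0:
        cor = float((((ii - mea_j) * (jj - mea_i) * P).sum())
                    / np.sqrt(var_i * var_j))
    else:
        cor = 0.0
    return {
        "Mea": mea_i,
        "Var": var_i,
        "Hom": float((P / (1.0 + diff**2)).sum()),
        "Con": float((diff**2 * P).sum()),
        "Dis": float((np.abs(diff) * P).sum()),
        "Ent": float(-(P * logP).sum()),
        "Sec": float((P**2).sum()),
        "Cor": cor,
    }


def _window_pairs(q: np.ndarray, direction: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-window co-occurring value pairs for 3x3 windows, one direction.

    Returns (A, B) of shape (k, H-2, W-2): the k in-window pixel pairs at
    the direction's distance-1 offset, for every valid window.
    """
    win = sliding_window_view(q, (3, 3))
    dr, dc = _OFFSETS[direction]
    aa, bb = [], []
    for u in range(3):
        for v in range(3):
            u2, v2 = u + dr, v + dc
            if 0 <= u2 < 3 and 0 <= v2 < 3:
                aa.append(win[:, :, u, v])
                bb.append(win[:, :, u2, v2])
    return np.stack(aa).astype(np.int64), np.stack(bb).astype(np.int64)


def _direction_images(q: np.ndarray, direction: int, levels: int) -> dict[str, np.ndarray]:
    """All eight texture images for one direction (vectorized over windows)."""
    A, B = _window_pairs(q, direction)
    k = A.shape[0]
    Af = A.astype(float)
    Bf = B.astype(float)
    # ordered symmetric pairs: expectations over 2k ordered pairs
    u = (Af.sum(axis=0) + Bf.sum(axis=0)) / (2 * k)
    d = Af - Bf
    con = (d**2).mean(axis=0)
    dis = np.abs(d).mean(axis=0)
    hom = (1.0 / (1.0 + d**2)).mean(axis=0)
    var = (((Af - u) ** 2).sum(axis=0) + ((Bf - u) ** 2).sum(axis=0)) / (2 * k)
    cov = ((Af - u) * (Bf - u)).mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        cor = np.where(var > 0, cov / np.where(var > 0, var, 1.0), 0.0)
    # Sec/Ent need cell probabilities: multiplicity of each unordered pair
    key = np.minimum(A, B) * levels + np.maximum(A, B)
    diag = (A == B)
    mult = np.zeros(key.shape, dtype=np.int64)
    for t in range(k):
        mult[t] = (key == key[t]).sum(axis=0)
    sec = (2.0 * mult * (1 + diag)).sum(axis=0) / (2.0 * k) ** 2
    ent = (np.log(2.0 * k) - np.log(mult) - diag * np.log(2.0)).sum(axis=0) / k
    return {"Mea": u, "Var": var, "Hom": hom, "Con": con, "Dis": dis,
            "Ent": ent, "Sec": sec, "Cor": cor}


def texture_images(
    q: np.ndarray, levels: int | None = None, directions=DIRECTIONS
) -> dict[str, np.ndarray]:
    """3x3 sliding-window texture images, averaged over the four directions.

    Output arrays have shape (H-2, W-2): edge pixels without a full window
    are skipped, no padding.
    """
    q = np.asarray(q)
    if q.ndim != 2 or min(q.shape) < 3:
        raise DomainError(f"raster must be at least 3x3, got {q.shape}")
    g = int(levels if levels is not None else q.max() + 1)
    acc: dict[str, np.ndarray] = {}
    for direction in directions:
        imgs = _direction_images(q, direction, g)
        for name, img in imgs.items():
            acc[name] = acc.get(name, 0.0) + img
    return {name: img / len(directions) for name, img in acc.items()}


def band_texture_image(
    q: np.ndarray, feature: str, levels: int | None = None
) -> np.ndarray:
    """One 4-direction-averaged texture image for a quantized band."""
    if feature not in FEATURES:
        raise ConfigurationError(f"feature must be one of {FEATURES}")
    return texture_images(q, levels)[feature]


def identity_names() -> list[str]:
    """The 48 texture identities in canonical (band-major, Table-2) order."""
    return [f"{feat}{band}" for band in range(1, 7) for feat in FEATURES]


def plot_texture(
    scene, mask: np.ndarray, levels: int = 32
) -> pd.DataFrame:
    """Plot-level texture values: 6 bands x 8 features over masked pixels.

    Returns a DataFrame with columns band (1..6, ascending wavelength),
    feature, identity (e.g. ``Sec5``) and value. The texture image is only
    defined on interior pixels, so the mask is cropped accordingly.
    """
    inner = np.asarray(mask)[1:-1, 1:-1]
    if not inner.any():
        raise DomainError("mask is empty after edge exclusion")
    rows = []
    for b in range(scene.reflectance.shape[0]):
        q = quantize_band(scene.reflectance[b], levels)
        imgs = texture_images(q, levels)
        for feat in FEATURES:
            rows.append({
                "band": b + 1,
                "feature": feat,
                "identity": f"{feat}{b + 1}",
                "value": float(imgs[feat][inner].mean()),
            })
    return pd.DataFrame(rows)


def texture_index(form: str, t1, t2):
    """One texture-index value; scalar or elementwise on arrays.

    Raises :class:`UndefinedValueError` for scalar inputs hitting a zero
    denominator; array inputs yield NaN at those positions.
    """
    scalar = np.isscalar(t1) and np.isscalar(t2)
    t1 = np.asarray(t1, dtype=float)
    t2 = np.asarray(t2, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        if form == "NDTI":
            den = t1 + t2
            val = np.where(den != 0, (t1 - t2) / np.where(den != 0, den, 1), np.nan)
        elif form == "DTI":
            val = t1 - t2
        elif form == "RTI":
            val = np.where(t2 != 0, t1 / np.where(t2 != 0, t2, 1), np.nan)
        elif form == "NTI":
            den = t1**2 + t2
            val = np.where(den != 0, (t1**2 - t2) / np.where(den != 0, den, 1),
                           np.nan)
        elif form == "RDTI":
            ok = (t1 != 0) & (t2 != 0)
            val = np.where(ok, 1.0 / np.where(t1 != 0, t1, 1)
                           - 1.0 / np.where(t2 != 0, t2, 1), np.nan)
        elif form == "RATI":
            ok = (t1 != 0) & (t2 != 0)
            val = np.where(ok, 1.0 / np.where(t1 != 0, t1, 1)
                           + 1.0 / np.where(t2 != 0, t2, 1), np.nan)
        else:
            raise ConfigurationError(f"unknown texture-index form {form!r}")
    if scalar:
        v = float(val)
        if not np.isfinite(v):
            raise UndefinedValueError(f"{form}({t1}, {t2}): zero denominator")
        return v
    return val


def _pearson_matrix(V: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Column-wise Pearson r of V (n, m) against y (n,); NaN where undefined."""
    ok = np.isfinite(V).all(axis=0)
    Vc = V - np.nanmean(V, axis=0)
    yc = y - y.mean()
    with np.errstate(divide="ignore", invalid="ignore"):
        num = (Vc * yc[:, None]).sum(axis=0)
        den = np.sqrt((Vc**2).sum(axis=0) * (yc**2).sum())
        r = np.where((den > 0) & ok, num / np.where(den > 0, den, 1), np.nan)
    return r


def search_texture_indices(
    texture_table: pd.DataFrame,
    smc: np.ndarray,
    forms=TI_FORMS,
) -> pd.DataFrame:
    """Exhaustive best-pair search per texture-index form.

    ``texture_table`` is plots x texture identities (columns in canonical
    order, e.g. from :func:`identity_names`); ``smc`` is the response for
    one depth layer. Every ordered pair (T1, T2) of identities — identical
    pairs included — is scored by |Pearson r|; the winner per form is
    returned (ties break to the first pair in band-major column order of T1
    then T2). Degenerate candidates (constant or undefined index vectors)
    are skipped with a warning.
    """
    y = np.asarray(smc, dtype=float)
    T = texture_table.to_numpy(dtype=float)
    n, m = T.shape
    if n < 3:
        raise DomainError("search requires at least 3 plots")
    if not np.isfinite(T).all():
        raise DomainError("texture table contains non-finite values")
    names = list(texture_table.columns)
    T1 = T[:, :, None]
    T2 = T[:, None, :]
    rows = []
    for form in forms:
        V = texture_index(form, np.broadcast_to(T1, (n, m, m)),
                          np.broadcast_to(T2, (n, m, m))).reshape(n, m * m)
        r = _pearson_matrix(V, y)
        if np.isnan(r).all():
            warnings.warn(f"{form}: every candidate pair degenerate", stacklevel=2)
            continue
        flat = np.where(np.isnan(r), -1.0, np.abs(r))
        best = int(flat.argmax())  # first max = lexicographic tie-break
        rows.append({
            "form": form,
            "t1": names[best // m],
            "t2": names[best % m],
            "r": float(r[best]),
        })
    if not rows:
        raise SearchError("texture-index search: all forms degenerate")
    return pd.DataFrame(rows)
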