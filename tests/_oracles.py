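"""Independent oracles shared by the texture and acceptance tests.

These deliberately avoid the package's sliding-window code path: GLCMs come
from scikit-image's pair counter and statistics are evaluated directly from
the matrix.
"""

import numpy as np
from skimage.feature import graycomatrix

ANGLE = {0: 0.0, 45: np.pi / 4, 90: np.pi / 2, 135: 3 * np.pi / 4}


def skimage_window_glcm(window, direction, levels):
    """Symmetric, normalized GLCM of one integer window via scikit-image."""
    m = graycomatrix(window.astype(np.uint8), distances=[1],
                     angles=[ANGLE[direction]], levels=levels,
                     symmetric=True, normed=True)
    return m[:, :, 0, 0]


def stats_from_matrix(P):
    """The eight texture statistics evaluated directly from a GLCM array."""
    g = P.shape[0]
    i = np.arange(g, dtype=float)
    pi, pj = P.sum(axis=1), P.sum(axis=0)
    mi, mj = i @ pi, i @ pj
    vi, vj = ((i - mi) ** 2) @ pi, ((i - mj) ** 2) @ pj
    ii, jj = np.meshgrid(i, i, indexing="ij")
    out = {
        "Mea": mi,
        "Var": vi,
        "Hom": (P / (1 + (ii - jj) ** 2)).sum(),
        "Con": ((ii - jj) ** 2 * P).sum(),
        "Dis": (np.abs(ii - jj) * P).sum(),
        "Ent": float(-(P[P > 0] * np.log(P[P > 0])).sum()),
        "Sec": (P**2).sum(),
    }
    out["Cor"] = (((ii - mj) * (jj - mi) * P).sum() / np.sqrt(vi * vj)
                  if vi > 0 and vj > 0 else 0.0)
    return out
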