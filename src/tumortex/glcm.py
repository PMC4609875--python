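"""3D gray-level co-occurrence matrices and the five Haralick-type statistics.

A co-occurrence matrix at displacement d·(dx,dy,dz) counts gray-level pairs
(G(v), G(v + d·offset)) over voxel pairs that both lie inside the mask. The
matrix is symmetrised (each pair counted in both orders), which makes the 13
half-neighbourhood directions equivalent to the full 26-neighbourhood and
gives the correlation statistic a single well-defined marginal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import QuantizedVOI

GLCM_FEATURE_NAMES = (
    "glcm_entropy",
    "glcm_homogeneity",
    "glcm_contrast",
    "glcm_energy",
    "glcm_correlation",
)


@dataclass
class CooccurrenceMatrix:
    """Symmetric normalized co-occurrence frequencies P[i, j] (levels 1..G)."""

    P: np.ndarray
    direction: tuple[int, int, int]
    distance: int
    pair_count: int  # directed in-mask voxel pairs found at this displacement


def compute_glcm(
    voi: QuantizedVOI, direction: np.ndarray | tuple, distance: int = 1
) -> CooccurrenceMatrix:
    """Co-occurrence matrix of ``voi`` at displacement ``distance * direction``.

    Both members of a pair must be in-mask. With no valid pairs, ``pair_count``
    is 0 and ``P`` is all-zero; callers skip such directions when averaging.
    """
    dx, dy, dz = (int(c) * distance for c in direction)
    g = voi.n_levels
    lev = voi.levels
    mask = voi.mask
    nx, ny, nz = lev.shape

    # overlapping slabs of the grid shifted by (dx,dy,dz)
    def sl(d, n):
        if d >= 0:
            return slice(0, n - d), slice(d, n)
        return slice(-d, n), slice(0, n + d)

    (ax, bx), (ay, by), (az, bz) = sl(dx, nx), sl(dy, ny), sl(dz, nz)
    if ax.start >= ax.stop or ay.start >= ay.stop or az.start >= az.stop:
        P = np.zeros((g, g))
        return CooccurrenceMatrix(P, tuple(int(c) for c in direction), distance, 0)

    m_pair = mask[ax, ay, az] & mask[bx, by, bz]
    i = lev[ax, ay, az][m_pair] - 1
    j = lev[bx, by, bz][m_pair] - 1
    counts = np.zeros((g, g), dtype=np.int64)
    np.add.at(counts, (i, j), 1)
    sym = counts + counts.T
    total = sym.sum()
    P = sym / total if total > 0 else sym.astype(float)
    return CooccurrenceMatrix(
        P=P,
        direction=tuple(int(c) for c in direction),
        distance=distance,
        pair_count=int(counts.sum()),
    )


def glcm_features(cm: CooccurrenceMatrix) -> dict[str, float]:
    """Entropy, homogeneity, contrast, energy and correlation of a GLCM.

    Entropy is −Σ P log₂ P; correlation uses the mean/variance of the
    symmetric marginal and is defined as 0 when that variance is zero.
    """
    if cm.pair_count <= 0:
        raise ValueError("no voxel pairs: features undefined")
    P = cm.P
    g = P.shape[0]
    i = np.arange(1, g + 1)
    I, J = np.meshgrid(i, i, indexing="ij")

    nz = P > 0
    entropy = float(-(P[nz] * np.log2(P[nz])).sum())
    homogeneity = float((P / (1.0 + np.abs(I - J))).sum())
    contrast = float(((I - J) ** 2 * P).sum())
    energy = float((P**2).sum())

    marginal = P.sum(axis=1)
    mu = float((i * marginal).sum())
    var = float(((i - mu) ** 2 * marginal).sum())
    if var > 0:
        correlation = float((((I - mu) * (J - mu) * P).sum()) / var)
    else:
        correlation = 0.0
    return {
        "glcm_entropy": entropy,
        "glcm_homogeneity": homogeneity,
        "glcm_contrast": contrast,
        "glcm_energy": energy,
        "glcm_correlation": correlation,
    }
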