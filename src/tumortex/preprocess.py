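"""3D Laplacian-of-Gaussian normalisation and gray-level quantization of a VOI.

The LoG ("Mexican hat") filter is a band-pass normalisation stage: it removes
slow intensity inhomogeneity and enhances blob-like structure at the scale set
by the kernel standard deviations. The quantizer maps in-mask intensities to
integer gray levels 1..G, the representation all texture extractors consume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class LoGParams:
    """Anisotropic 3D LoG kernel parameters.

    sigma_x/y/z are the Gaussian standard deviations in voxels, ``gain`` a
    scalar factor, ``kernel_radius`` the truncation half-width in voxels
    (must be at least 3x the largest sigma so the truncated tails are
    negligible; default 4x).
    """

    sigma_x: float = 1.0
    sigma_y: float = 1.0
    sigma_z: float = 1.0
    gain: float = 1.0
    kernel_radius: int | None = None

    def __post_init__(self):
        if min(self.sigma_x, self.sigma_y, self.sigma_z) <= 0:
            raise ValueError("LoG standard deviations must be positive")
        if self.kernel_radius is None:
            object.__setattr__(
                self, "kernel_radius", int(math.ceil(4 * self.max_sigma))
            )
        if self.kernel_radius < 3 * self.max_sigma:
            raise ValueError("kernel_radius must be >= 3 x max(sigma)")

    @property
    def max_sigma(self) -> float:
        return max(self.sigma_x, self.sigma_y, self.sigma_z)


def log_value(x, y, z, params: LoGParams):
    """Closed-form LoG value at continuous offset (x, y, z) from the kernel centre.

    C * [(x²/σx⁴ − 1/σx²) + (y²/σy⁴ − 1/σy²) + (z²/σz⁴ − 1/σz²)]
      * exp(−x²/2σx² − y²/2σy² − z²/2σz²)
    """
    sx2 = params.sigma_x**2
    sy2 = params.sigma_y**2
    sz2 = params.sigma_z**2
    poly = (
        (np.asarray(x) ** 2 / sx2**2 - 1.0 / sx2)
        + (np.asarray(y) ** 2 / sy2**2 - 1.0 / sy2)
        + (np.asarray(z) ** 2 / sz2**2 - 1.0 / sz2)
    )
    gauss = np.exp(
        -np.asarray(x) ** 2 / (2 * sx2)
        - np.asarray(y) ** 2 / (2 * sy2)
        - np.asarray(z) ** 2 / (2 * sz2)
    )
    return params.gain * poly * gauss


def log_kernel(params: LoGParams, zero_dc: bool = True) -> np.ndarray:
    """Sampled LoG kernel on the integer grid [-r, r]³.

    The continuous LoG integrates to zero but truncation breaks this, so the
    discrete kernel is mean-subtracted by default: constant inputs then map
    exactly to zero (DC-free contract).
    """
    r = params.kernel_radius
    ax = np.arange(-r, r + 1)
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    k = log_value(x, y, z, params)
    if zero_dc:
        k = k - k.mean()
    return k


def log_filter(volume: np.ndarray, params: LoGParams) -> np.ndarray:
    """Convolve a 3D volume with the (DC-free) LoG kernel, reflecting at borders."""
    volume = np.asarray(volume, dtype=float)
    if volume.ndim != 3:
        raise ValueError("expected a 3D volume")
    k = log_kernel(params)
    if any(ks > vs for ks, vs in zip(k.shape, volume.shape)):
        raise ValueError(
            f"LoG kernel {k.shape} larger than volume {volume.shape}"
        )
    return ndimage.convolve(volume, k, mode="reflect")


@dataclass
class QuantizedVOI:
    """A masked, gray-level-quantized voxel set.

    ``levels`` is a full-grid integer array: 1..n_levels inside the mask and 0
    outside. ``longest_edge`` (L) is the longest edge of the mask bounding box;
    co-occurrence distances are meaningful for d in 1..L/2.
    """

    levels: np.ndarray
    mask: np.ndarray
    n_levels: int
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    _bbox: tuple = field(init=False, repr=False)

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.levels.shape != self.mask.shape:
            raise ValueError("levels and mask shapes differ")
        if not self.mask.any():
            raise ValueError("empty mask")
        idx = np.nonzero(self.mask)
        self._bbox = tuple((int(a.min()), int(a.max())) for a in idx)

    @property
    def coords(self) -> np.ndarray:
        """(n, 3) integer coordinates of in-mask voxels."""
        return np.argwhere(self.mask)

    @property
    def voxel_levels(self) -> np.ndarray:
        """Gray levels of the in-mask voxels, in ``coords`` order."""
        return self.levels[self.mask]

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def bounding_box(self) -> tuple:
        """((x0,x1), (y0,y1), (z0,z1)) inclusive bounds of the mask support."""
        return self._bbox

    @property
    def longest_edge(self) -> int:
        return max(hi - lo + 1 for lo, hi in self._bbox)


def quantize(
    volume: np.ndarray,
    mask: np.ndarray,
    n_levels: int = 16,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> QuantizedVOI:
    """Min-max quantize the in-mask intensities into gray levels 1..n_levels.

    Binning is linear over the in-mask range only; the maximum maps to
    n_levels. A constant in-mask region maps entirely to level 1.
    """
    if n_levels < 2:
        raise ValueError("need at least 2 gray levels")
    mask = np.asarray(mask, dtype=bool)
    volume = np.asarray(volume, dtype=float)
    if volume.shape != mask.shape:
        raise ValueError("volume and mask shapes differ")
    if not mask.any():
        raise ValueError("empty mask")
    vals = volume[mask]
    lo, hi = float(vals.min()), float(vals.max())
    levels = np.zeros(volume.shape, dtype=np.int32)
    if hi > lo:
        q = 1 + np.floor((volume[mask] - lo) / (hi - lo) * n_levels)
        levels[mask] = np.minimum(q, n_levels).astype(np.int32)
    else:
        levels[mask] = 1
    return QuantizedVOI(levels=levels, mask=mask, n_levels=n_levels, spacing=spacing)
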