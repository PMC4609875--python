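"""Centroid-line gray-level distribution features (volumetric SCLGM).

Thirteen digital lines are drawn through the VOI centroid, one per direction
offset, each clipped to the mask. The ordered gray levels along each line form
a profile; 12 distributional statistics summarise the pooled profile and the
13 per-line profiles (aggregated across lines by mean/min/max/range), plus the
mean line length — 61 features in total.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .directions import build_direction_table
from .preprocess import QuantizedVOI

STAT_NAMES = (
    "mean",
    "variance",
    "mad",
    "std",
    "skewness",
    "kurtosis",
    "median",
    "min",
    "max",
    "range",
    "energy",
    "entropy",
)
AGG_NAMES = ("mean", "min", "max", "range")

SCLGM_FEATURE_NAMES: tuple[str, ...] = (
    tuple(f"sclgm_pooled_{s}" for s in STAT_NAMES)
    + tuple(f"sclgm_line_{s}_{a}" for s in STAT_NAMES for a in AGG_NAMES)
    + ("sclgm_mean_line_length",)
)
assert len(SCLGM_FEATURE_NAMES) == 61


@dataclass
class CentroidLineSet:
    """The 13 ordered gray-level profiles through the VOI centroid."""

    lines: list[np.ndarray]
    centroid: tuple[int, int, int]
    n_levels: int

    @property
    def line_lengths(self) -> np.ndarray:
        return np.array([len(c) for c in self.lines])


def _round_half_down(x: np.ndarray) -> np.ndarray:
    # exact .5 breaks toward the lower index
    return np.ceil(np.asarray(x) - 0.5).astype(int)


def extract_centroid_lines(voi: QuantizedVOI) -> CentroidLineSet:
    """Digital lines through the centroid along the 13 direction offsets.

    The centroid is the rounded mean in-mask coordinate. Each line steps in
    integer multiples of ±offset across the bounding box; its profile is the
    ordered gray levels of the in-mask voxels it crosses. A line that misses
    the mask entirely (possible for thin or concave masks whose rounded
    centroid falls outside) falls back to the level of the in-mask voxel
    nearest the centroid.
    """
    coords = voi.coords
    c = _round_half_down(coords.mean(axis=0))
    table = build_direction_table()
    (x0, x1), (y0, y1), (z0, z1) = voi.bounding_box
    lev, mask = voi.levels, voi.mask

    nearest = None
    lines: list[np.ndarray] = []
    for off in table.offsets:
        # parameter range of t such that c + t*off stays inside the bbox
        tmin, tmax = -10**9, 10**9
        for ci, oi, lo, hi in (
            (c[0], off[0], x0, x1),
            (c[1], off[1], y0, y1),
            (c[2], off[2], z0, z1),
        ):
            if oi == 0:
                if not (lo <= ci <= hi):
                    tmin, tmax = 0, -1
                continue
            a = (lo - ci) / oi
            b = (hi - ci) / oi
            lo_t, hi_t = min(a, b), max(a, b)
            tmin = max(tmin, int(np.ceil(lo_t)))
            tmax = min(tmax, int(np.floor(hi_t)))
        profile = []
        for t in range(tmin, tmax + 1):
            x, y, z = c + t * off
            if mask[x, y, z]:
                profile.append(int(lev[x, y, z]))
        if not profile:
            if nearest is None:
                d2 = ((coords - c) ** 2).sum(axis=1)
                nc = coords[int(np.argmin(d2))]
                nearest = int(lev[tuple(nc)])
            profile = [nearest]
        lines.append(np.array(profile, dtype=int))
    return CentroidLineSet(lines=lines, centroid=tuple(int(v) for v in c), n_levels=voi.n_levels)


def profile_statistics(values: np.ndarray, n_levels: int) -> dict[str, float]:
    """The 12 distributional statistics of a gray-level profile.

    Moments use population (n) normalisation; skewness and kurtosis of a
    zero-variance profile are defined as 0, kurtosis is excess. Energy and
    entropy are computed on the normalised gray-level histogram (base-2
    entropy).
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty profile")
    mean = v.mean()
    var = v.var()  # population
    std = np.sqrt(var)
    mad = np.abs(v - mean).mean()
    if var > 0:
        skew = ((v - mean) ** 3).mean() / std**3
        kurt = ((v - mean) ** 4).mean() / var**2 - 3.0
    else:
        skew = kurt = 0.0
    hist = np.bincount(values.astype(int), minlength=n_levels + 1)[1:].astype(float)
    prob = hist / hist.sum()
    nz = prob > 0
    energy = float((prob**2).sum())
    entropy = float(-(prob[nz] * np.log2(prob[nz])).sum())
    return {
        "mean": float(mean),
        "variance": float(var),
        "mad": float(mad),
        "std": float(std),
        "skewness": float(skew),
        "kurtosis": float(kurt),
        "median": float(np.median(v)),
        "min": float(v.min()),
        "max": float(v.max()),
        "range": float(v.max() - v.min()),
        "energy": energy,
        "entropy": entropy,
    }


def sclgm_features(lines: CentroidLineSet) -> dict[str, float]:
    """The 61 centroid-line features: 12 pooled + 12x4 line-aggregated + mean length."""
    if any(len(c) == 0 for c in lines.lines):
        raise ValueError("empty centroid line")
    pooled = profile_statistics(np.concatenate(lines.lines), lines.n_levels)
    per_line = [profile_statistics(c, lines.n_levels) for c in lines.lines]

    out: dict[str, float] = {f"sclgm_pooled_{s}": pooled[s] for s in STAT_NAMES}
    for s in STAT_NAMES:
        col = np.array([d[s] for d in per_line])
        out[f"sclgm_line_{s}_mean"] = float(col.mean())
        out[f"sclgm_line_{s}_min"] = float(col.min())
        out[f"sclgm_line_{s}_max"] = float(col.max())
        out[f"sclgm_line_{s}_range"] = float(col.max() - col.min())
    out["sclgm_mean_line_length"] = float(lines.line_lengths.mean())
    return out
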