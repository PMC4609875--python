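"""Gray-level run-length matrices and the eleven Galloway/Chu statistics.

A run is a maximal sequence of consecutive voxels of equal gray level along a
lattice line parallel to one of the 13 direction offsets. Runs are restricted
to in-mask voxels; a mask gap breaks a run even though the lattice line
continues. p(i, j) counts runs of gray level i and length j; nr = Σ p(i, j).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import QuantizedVOI

RLM_FEATURE_NAMES = (
    "rlm_sre",
    "rlm_lre",
    "rlm_lgre",
    "rlm_hgre",
    "rlm_srlge",
    "rlm_srhge",
    "rlm_lrlge",
    "rlm_lrhge",
    "rlm_glnu",
    "rlm_rlnu",
    "rlm_rpc",
)


@dataclass
class RunLengthMatrix:
    """Run counts p[i-1, j-1] for gray level i (1..G) and run length j (1..N)."""

    p: np.ndarray
    nr: int
    direction: tuple[int, int, int]

    @property
    def n_voxels_covered(self) -> int:
        j = np.arange(1, self.p.shape[1] + 1)
        return int((self.p * j).sum())


def compute_rlm(voi: QuantizedVOI, direction: np.ndarray | tuple) -> RunLengthMatrix:
    """Run-length matrix of ``voi`` along lattice lines parallel to ``direction``."""
    off = tuple(int(c) for c in direction)
    if off == (0, 0, 0):
        raise ValueError("zero direction")
    (x0, x1), (y0, y1), (z0, z1) = voi.bounding_box
    lev = voi.levels
    mask = voi.mask
    max_len = voi.longest_edge

    def in_box(x, y, z):
        return x0 <= x <= x1 and y0 <= y <= y1 and z0 <= z <= z1

    runs: dict[tuple[int, int], int] = {}

    def close(level, length):
        if length > 0:
            runs[(level, length)] = runs.get((level, length), 0) + 1

    # line starts: bbox voxels whose predecessor along the offset is outside the bbox
    for x in range(x0, x1 + 1):
        for y in range(y0, y1 + 1):
            for z in range(z0, z1 + 1):
                if in_box(x - off[0], y - off[1], z - off[2]):
                    continue
                cx, cy, cz = x, y, z
                cur_level, cur_len = 0, 0
                while in_box(cx, cy, cz):
                    if mask[cx, cy, cz]:
                        g = int(lev[cx, cy, cz])
                        if g == cur_level:
                            cur_len += 1
                        else:
                            close(cur_level, cur_len)
                            cur_level, cur_len = g, 1
                    else:
                        close(cur_level, cur_len)
                        cur_level, cur_len = 0, 0
                    cx, cy, cz = cx + off[0], cy + off[1], cz + off[2]
                close(cur_level, cur_len)

    p = np.zeros((voi.n_levels, max_len), dtype=np.int64)
    for (g, length), c in runs.items():
        if length > p.shape[1]:  # diagonal lines can exceed the longest edge
            p = np.pad(p, ((0, 0), (0, length - p.shape[1])))
        p[g - 1, length - 1] += c
    return RunLengthMatrix(p=p, nr=int(p.sum()), direction=off)


def rlm_features(rlm: RunLengthMatrix) -> dict[str, float]:
    """The 11 run-length statistics (SRE..LRHGE, GLNU, RLNU, RPC)."""
    if rlm.nr <= 0:
        raise ValueError("no runs: features undefined")
    p = rlm.p.astype(float)
    nr = float(rlm.nr)
    g = np.arange(1, p.shape[0] + 1)[:, None]  # gray level i
    j = np.arange(1, p.shape[1] + 1)[None, :]  # run length j

    sre = (p / j**2).sum() / nr
    lre = (p * j**2).sum() / nr
    lgre = (p / g**2).sum() / nr
    hgre = (p * g**2).sum() / nr
    srlge = (p / (g**2 * j**2)).sum() / nr
    srhge = (p * g**2 / j**2).sum() / nr
    lrlge = (p * j**2 / g**2).sum() / nr
    lrhge = (p * g**2 * j**2).sum() / nr
    glnu = (p.sum(axis=1) ** 2).sum() / nr
    rlnu = (p.sum(axis=0) ** 2).sum() / nr
    rpc = nr / (p * j).sum()
    return dict(
        zip(
            RLM_FEATURE_NAMES,
            (float(v) for v in (sre, lre, lgre, hgre, srlge, srhge, lrlge, lrhge, glnu, rlnu, rpc)),
        )
    )
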