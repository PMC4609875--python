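"""The 13 canonical displacement directions of a 3D voxel neighbourhood.

A voxel has 26 neighbours; taking one offset from each antipodal pair gives
13 directions. Co-occurrence and run-length statistics scanned along these 13
offsets (with symmetrisation / bidirectional runs) cover the full
26-neighbourhood, and the same offsets orient the 13 centroid lines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# (dx, dy, dz) offset and its (theta, phi) direction label in degrees,
# in canonical row order.
_ROWS: list[tuple[tuple[int, int, int], tuple[int, int]]] = [
    ((0, 1, 0), (0, 0)),
    ((-1, 1, 0), (45, 0)),
    ((-1, 0, 0), (90, 0)),
    ((-1, -1, 0), (135, 0)),
    ((0, 1, -1), (0, 45)),
    ((0, 0, -1), (0, 90)),
    ((0, -1, -1), (0, 135)),
    ((-1, 0, -1), (90, 45)),
    ((1, 0, -1), (90, 135)),
    ((-1, 1, -1), (45, 45)),
    ((1, -1, -1), (45, 135)),
    ((-1, -1, -1), (135, 45)),
    ((1, 1, -1), (135, 135)),
]


@dataclass(frozen=True)
class DirectionTable:
    """The 13 direction offsets with their (theta, phi) angle labels."""

    offsets: np.ndarray = field(
        default_factory=lambda: np.array([r[0] for r in _ROWS], dtype=int)
    )
    angles: tuple[tuple[int, int], ...] = tuple(r[1] for r in _ROWS)

    def __len__(self) -> int:
        return len(self.offsets)

    def __iter__(self):
        return iter(self.offsets)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("index\tdx\tdy\tdz\ttheta_deg\tphi_deg\n")
            for k, (off, (th, ph)) in enumerate(zip(self.offsets, self.angles), 1):
                fh.write(f"{k}\t{off[0]}\t{off[1]}\t{off[2]}\t{th}\t{ph}\n")


def build_direction_table() -> DirectionTable:
    """Return the canonical 13-direction table (offsets in (x, y, z) index space)."""
    return DirectionTable()
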