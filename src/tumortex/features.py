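"""The 77-feature volumetric texture descriptor.

Layout (fixed order): 61 centroid-line (SCLGM) features, then 5 co-occurrence
features averaged over the 13 directions and the evaluated distance set, then
11 run-length features averaged over the 13 directions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .directions import build_direction_table
from .glcm import GLCM_FEATURE_NAMES, compute_glcm, glcm_features
from .preprocess import QuantizedVOI
from .rlm import RLM_FEATURE_NAMES, compute_rlm, rlm_features
from .sclgm import SCLGM_FEATURE_NAMES, extract_centroid_lines, sclgm_features

FEATURE_NAMES: tuple[str, ...] = (
    SCLGM_FEATURE_NAMES + GLCM_FEATURE_NAMES + RLM_FEATURE_NAMES
)

BLOCKS = {
    "sclgm": SCLGM_FEATURE_NAMES,
    "glcm": GLCM_FEATURE_NAMES,
    "rlm": RLM_FEATURE_NAMES,
}


@dataclass
class FeatureVector:
    """Named 77-slot texture descriptor of one VOI."""

    values: np.ndarray
    names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.names),):
            raise ValueError("value/name length mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate feature names")

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])

    def block(self, name: str) -> dict[str, float]:
        want = BLOCKS[name]
        return {n: self[n] for n in want}

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.names))


def default_distances(voi: QuantizedVOI) -> tuple[int, ...]:
    """Default co-occurrence distance set {1, 2}, clipped to the valid 1..L/2 range."""
    dmax = max(1, voi.longest_edge // 2)
    return tuple(d for d in (1, 2) if d <= dmax) or (1,)


def extract_all(
    voi: QuantizedVOI, distances: tuple[int, ...] | None = None
) -> FeatureVector:
    """Full 77-feature descriptor of a quantized VOI.

    GLCM features are averaged over all (direction, distance) combinations
    that produce at least one voxel pair, run-length features over the 13
    directions; the SCLGM block is appended unaveraged.
    """
    if distances is None:
        distances = default_distances(voi)
    dmax = max(1, voi.longest_edge // 2)
    for d in distances:
        if not 1 <= d <= max(1, dmax):
            raise ValueError(f"distance {d} outside 1..L/2 = 1..{dmax}")
    table = build_direction_table()

    glcm_rows = []
    for off in table.offsets:
        for d in distances:
            cm = compute_glcm(voi, off, d)
            if cm.pair_count > 0:
                glcm_rows.append(glcm_features(cm))
    if not glcm_rows:
        raise ValueError("no voxel pairs at any direction/distance")
    glcm_mean = {
        n: float(np.mean([r[n] for r in glcm_rows])) for n in GLCM_FEATURE_NAMES
    }

    rlm_rows = []
    for off in table.offsets:
        rm = compute_rlm(voi, off)
        if rm.nr > 0:
            rlm_rows.append(rlm_features(rm))
    rlm_mean = {n: float(np.mean([r[n] for r in rlm_rows])) for n in RLM_FEATURE_NAMES}

    sclgm = sclgm_features(extract_centroid_lines(voi))

    merged = {**sclgm, **glcm_mean, **rlm_mean}
    return FeatureVector(values=np.array([merged[n] for n in FEATURE_NAMES]))


def extract_table(
    vois: list[QuantizedVOI],
    labels: list[int],
    ids: list[str] | None = None,
    distances: tuple[int, ...] | None = None,
) -> pd.DataFrame:
    """Feature table with one row per subject: id, label, 77 named columns."""
    if ids is None:
        ids = [f"subj{i:03d}" for i in range(len(vois))]
    rows = []
    for sid, lab, voi in zip(ids, labels, vois):
        fv = extract_all(voi, distances=distances)
        rows.append({"id": sid, "label": int(lab), **dict(zip(fv.names, fv.values))})
    return pd.DataFrame(rows)


def write_feature_table(df: pd.DataFrame, csv_path=None, h5_path=None) -> None:
    """Persist a feature table as CSV and/or HDF5."""
    if csv_path is not None:
        df.to_csv(csv_path, index=False)
    if h5_path is not None:
        import h5py

        with h5py.File(h5_path, "w") as f:
            f.create_dataset("features", data=df[list(FEATURE_NAMES)].to_numpy())
            f.create_dataset("label", data=df["label"].to_numpy())
            f.create_dataset(
                "id", data=np.array(df["id"], dtype=h5py.string_dtype())
            )
            f.attrs["feature_names"] = list(FEATURE_NAMES)
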