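"""Synthetic textured phantoms and tabular datasets with known structure.

Volumetric phantoms carry an ellipsoidal "lesion" whose texture is a smoothed
Gaussian noise field: white noise convolved with an isotropic Gaussian of the
class correlation length, rescaled to the class mean and standard deviation.
The correlation length is the texture dial — larger values give coarser, more
spatially coherent texture (higher neighbour co-occurrence similarity, longer
gray-level runs). The tabular generator produces labeled Gaussian feature
vectors with a known informative subset, a controlled test bed for wrapper
feature selection.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class ClassTexture:
    """Texture controls of one lesion class."""

    mean: float
    corr_len: float  # Gaussian smoothing sigma in voxels (0 = white noise)
    noise_std: float


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, per-class texture controls and cohort size of a phantom study.

    Defaults: 32³ grid, ellipsoid semi-axes (10, 8, 6) voxels, benign (−1)
    texture finer (corr_len 1.0) and malignant (+1) coarser (corr_len 2.5)
    with a modest mean offset, both over an independent-noise background.
    """

    shape: tuple[int, int, int] = (32, 32, 32)
    lesion_axes: tuple[float, float, float] = (10.0, 8.0, 6.0)
    class_params: dict[int, ClassTexture] = field(
        default_factory=lambda: {
            -1: ClassTexture(mean=100.0, corr_len=1.0, noise_std=20.0),
            +1: ClassTexture(mean=110.0, corr_len=2.5, noise_std=20.0),
        }
    )
    background_mean: float = 60.0
    background_std: float = 15.0
    n_subjects_per_class: int = 10
    seed: int = 0

    def __post_init__(self):
        if min(self.shape) < 8:
            raise ValueError("grid dimensions must be >= 8 voxels")
        if any(2 * a >= s for a, s in zip(self.lesion_axes, self.shape)):
            raise ValueError("lesion does not fit inside the grid")
        if set(self.class_params) != {-1, +1}:
            raise ValueError("class_params must define labels -1 and +1")
        a, b = self.class_params[-1], self.class_params[+1]
        if (a.mean, a.corr_len, a.noise_std) == (b.mean, b.corr_len, b.noise_std):
            raise ValueError("the two classes must differ in at least one texture control")
        if self.n_subjects_per_class < 1:
            raise ValueError("need at least one subject per class")


@dataclass
class LabeledVolume:
    """A scalar volume, its binary VOI mask, and a class label in {+1, −1}."""

    volume: np.ndarray
    mask: np.ndarray
    label: int
    subject_id: str = ""

    def __post_init__(self):
        if self.volume.shape != self.mask.shape:
            raise ValueError("volume and mask shapes differ")
        if not self.mask.any():
            raise ValueError("empty mask")
        if self.label not in (-1, 1):
            raise ValueError("label must be +1 or -1")


def ellipsoid_mask(shape, axes, center=None) -> np.ndarray:
    if center is None:
        center = tuple((s - 1) / 2 for s in shape)
    grids = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, axes))
    return r2 <= 1.0


def generate_phantom(spec: PhantomSpec, label: int, seed: int) -> LabeledVolume:
    """One phantom volume: class-textured ellipsoidal lesion over a noisy background.

    The lesion field is white noise smoothed at the class correlation length,
    standardised and scaled to (mean, noise_std); with noise_std 0 every lesion
    voxel equals the class mean exactly. Reproducible given (spec, label, seed).
    """
    if label not in spec.class_params:
        raise ValueError(f"unknown label {label}")
    rng = np.random.default_rng(seed)
    params = spec.class_params[label]
    mask = ellipsoid_mask(spec.shape, spec.lesion_axes)

    background = rng.normal(spec.background_mean, spec.background_std, spec.shape)
    field_ = rng.standard_normal(spec.shape)
    if params.corr_len > 0:
        field_ = ndimage.gaussian_filter(field_, sigma=params.corr_len)
    s = field_.std()
    if s > 0:
        field_ = field_ / s
    lesion = params.mean + params.noise_std * field_

    volume = np.where(mask, lesion, background)
    return LabeledVolume(volume=volume, mask=mask, label=label)


def generate_cohort(spec: PhantomSpec, seed: int | None = None) -> list[LabeledVolume]:
    """Balanced cohort; per-subject sub-seeds are counter offsets from the master seed."""
    base = spec.seed if seed is None else seed
    cohort = []
    counter = 0
    for label in (+1, -1):
        for i in range(spec.n_subjects_per_class):
            lv = generate_phantom(spec, label, seed=base + counter)
            lv.subject_id = f"{'mal' if label > 0 else 'ben'}{i:03d}"
            cohort.append(lv)
            counter += 1
    return cohort


@dataclass
class TabularDataset:
    """Labeled feature matrix whose class signal lives only in ``informative_idx``."""

    features: np.ndarray
    labels: np.ndarray
    informative_idx: np.ndarray
    feature_names: tuple[str, ...]
    seed: int


def generate_tabular(
    n: int, d: int, k: int, effect: float, seed: int
) -> TabularDataset:
    """n labeled d-dimensional Gaussian vectors; k informative columns.

    Class-conditional unit Gaussians; the informative columns of the +1 class
    are shifted by ``effect`` (in units of the noise standard deviation), the
    remaining columns are identically distributed in both classes. Labels are
    balanced ±1.
    """
    if k > d:
        raise ValueError("k informative features cannot exceed d")
    rng = np.random.default_rng(seed)
    labels = np.ones(n, dtype=int)
    labels[n // 2 :] = -1
    informative = np.sort(rng.choice(d, size=k, replace=False))
    X = rng.standard_normal((n, d))
    X[np.ix_(labels == 1, informative)] += effect
    names = tuple(f"f{i:02d}" for i in range(d))
    return TabularDataset(
        features=X, labels=labels, informative_idx=informative,
        feature_names=names, seed=seed,
    )


def write_cohort(cohort: list[LabeledVolume], out_dir) -> Path:
    """Write NIfTI volume + mask per subject and a CSV manifest; returns manifest path."""
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = out / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["subject_id", "label", "volume", "mask"])
        for lv in cohort:
            vpath = out / f"{lv.subject_id}_vol.nii"
            mpath = out / f"{lv.subject_id}_mask.nii"
            affine = np.eye(4)
            nib.save(nib.Nifti1Image(lv.volume.astype(np.float32), affine), vpath)
            nib.save(nib.Nifti1Image(lv.mask.astype(np.uint8), affine), mpath)
            w.writerow([lv.subject_id, lv.label, vpath.name, mpath.name])
    return manifest


def read_cohort(manifest_path) -> list[LabeledVolume]:
    """Load a cohort back from a manifest written by :func:`write_cohort`."""
    import nibabel as nib

    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    cohort = []
    with open(manifest_path) as fh:
        for row in csv.DictReader(fh):
            vol = np.asanyarray(nib.load(root / row["volume"]).dataobj, dtype=float)
            mask = np.asanyarray(nib.load(root / row["mask"]).dataobj) > 0
            cohort.append(
                LabeledVolume(
                    volume=vol, mask=mask, label=int(row["label"]),
                    subject_id=row["subject_id"],
                )
            )
    return cohort
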