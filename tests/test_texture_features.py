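"""Co-occurrence, run-length and centroid-line extractors against independent
brute-force oracles and hand-computed examples."""

import itertools

import numpy as np
import pytest

from tumortex.directions import build_direction_table
from tumortex.features import FEATURE_NAMES, extract_all
from tumortex.glcm import CooccurrenceMatrix, compute_glcm, glcm_features
from tumortex.preprocess import QuantizedVOI
from tumortex.rlm import compute_rlm, rlm_features
from tumortex.sclgm import (
    SCLGM_FEATURE_NAMES,
    extract_centroid_lines,
    profile_statistics,
    sclgm_features,
)

from conftest import line_voi, random_voi


# ---------------------------------------------------------------- oracles


def brute_glcm(voi, offset, d):
    """Triple-loop symmetric pair counter."""
    g = voi.n_levels
    counts = np.zeros((g, g), dtype=int)
    off = np.asarray(offset) * d
    shape = voi.mask.shape
    for v in np.argwhere(voi.mask):
        w = v + off
        if np.all(w >= 0) and np.all(w < shape) and voi.mask[tuple(w)]:
            i, j = voi.levels[tuple(v)] - 1, voi.levels[tuple(w)] - 1
            counts[i, j] += 1
            counts[j, i] += 1
    return counts


def brute_rlm(voi, offset):
    """Group in-mask voxels by lattice line, split runs on gaps and level changes."""
    off = np.asarray(offset)
    lines = {}
    for v in np.argwhere(voi.mask):
        # canonical line key: project out the offset direction by walking back
        t = 0
        w = v.copy()
        while True:
            w2 = w - off
            if np.all(w2 >= 0) and np.all(w2 < voi.mask.shape):
                w, t = w2, t + 1
            else:
                break
        lines.setdefault(tuple(w), []).append((t, int(voi.levels[tuple(v)])))
    runs = {}
    for pts in lines.values():
        pts.sort()
        prev_t, prev_g, length = None, None, 0
        for t, g in pts:
            if prev_t is not None and t == prev_t + 1 and g == prev_g:
                length += 1
            else:
                if length:
                    runs[(prev_g, length)] = runs.get((prev_g, length), 0) + 1
                length = 1
            prev_t, prev_g = t, g
        if length:
            runs[(prev_g, length)] = runs.get((prev_g, length), 0) + 1
    return runs


def test_glcm_matches_bruteforce_on_random_volumes(rng):
    table = build_direction_table()
    for rep in range(100):
        voi = random_voi(rng)
        off = table.offsets[rep % 13]
        d = 1 + rep % 2
        cm = compute_glcm(voi, off, d)
        counts = brute_glcm(voi, off, d)
        assert cm.pair_count * 2 == counts.sum()
        if counts.sum() > 0:
            assert np.allclose(cm.P, counts / counts.sum())
        else:
            assert np.all(cm.P == 0)


def test_rlm_matches_bruteforce_on_random_volumes(rng):
    table = build_direction_table()
    for rep in range(100):
        voi = random_voi(rng)
        off = table.offsets[rep % 13]
        rm = compute_rlm(voi, off)
        expected = brute_rlm(voi, off)
        got = {
            (i + 1, j + 1): int(rm.p[i, j])
            for i, j in zip(*np.nonzero(rm.p))
        }
        assert got == expected
        # conservation: total run length covers every in-mask voxel once
        assert rm.n_voxels_covered == voi.n_voxels


# ---------------------------------------------------------------- directions


class TestDirections:
    def test_thirteen_rows_first_and_last(self):
        t = build_direction_table()
        assert len(t) == 13
        assert tuple(t.offsets[0]) == (0, 1, 0) and t.angles[0] == (0, 0)
        assert tuple(t.offsets[12]) == (1, 1, -1) and t.angles[12] == (135, 135)

    def test_offsets_and_negations_cover_26_neighbourhood(self):
        t = build_direction_table()
        offs = {tuple(o) for o in t.offsets}
        negs = {tuple(-o) for o in t.offsets}
        assert not offs & negs
        all26 = {
            v for v in itertools.product((-1, 0, 1), repeat=3) if v != (0, 0, 0)
        }
        assert offs | negs == all26


# ---------------------------------------------------------------- glcm features


class TestGLCMFeatures:
    def test_hand_computed_two_cell_matrix(self):
        voi = line_voi([1, 2, 1])
        cm = compute_glcm(voi, (0, 1, 0), 1)
        assert cm.P[0, 1] == pytest.approx(0.5)
        assert cm.P[1, 0] == pytest.approx(0.5)
        f = glcm_features(cm)
        assert f["glcm_contrast"] == pytest.approx(1.0)
        assert f["glcm_energy"] == pytest.approx(0.5)
        assert f["glcm_homogeneity"] == pytest.approx(0.5)
        assert f["glcm_correlation"] == pytest.approx(-1.0)
        assert f["glcm_entropy"] == pytest.approx(1.0)  # two equiprobable cells

    def test_constant_voi_single_cell(self):
        voi = line_voi([2, 2, 2])
        cm = compute_glcm(voi, (0, 1, 0), 1)
        f = glcm_features(cm)
        assert cm.P[1, 1] == pytest.approx(1.0)
        assert f["glcm_energy"] == pytest.approx(1.0)
        assert f["glcm_contrast"] == pytest.approx(0.0)
        assert f["glcm_entropy"] == pytest.approx(0.0)
        assert f["glcm_correlation"] == 0.0  # degenerate marginal convention

    def test_uniform_four_cell_entropy_two_bits(self):
        P = np.zeros((3, 3))
        P[0, 1] = P[1, 0] = P[1, 2] = P[2, 1] = 0.25
        cm = CooccurrenceMatrix(P=P, direction=(0, 1, 0), distance=1, pair_count=4)
        assert glcm_features(cm)["glcm_entropy"] == pytest.approx(2.0)

    def test_no_pairs_raises(self):
        voi = line_voi([1])
        cm = compute_glcm(voi, (0, 1, 0), 1)
        assert cm.pair_count == 0
        with pytest.raises(ValueError):
            glcm_features(cm)


# ---------------------------------------------------------------- rlm features


class TestRLMFeatures:
    def test_hand_enumerated_runs(self):
        voi = line_voi([1, 1, 2, 2])
        rm = compute_rlm(voi, (0, 1, 0))
        assert rm.nr == 2
        assert rm.p[0, 1] == 1 and rm.p[1, 1] == 1
        f = rlm_features(rm)
        assert f["rlm_sre"] == pytest.approx(0.25)
        assert f["rlm_lre"] == pytest.approx(4.0)
        assert f["rlm_rpc"] == pytest.approx(0.5)

    def test_single_voxel_degenerate(self):
        voi = line_voi([1])
        rm = compute_rlm(voi, (0, 1, 0))
        assert rm.nr == 1
        f = rlm_features(rm)
        assert f["rlm_sre"] == 1.0
        assert f["rlm_lre"] == 1.0
        assert f["rlm_rpc"] == 1.0

    def test_constant_line_is_one_run(self):
        voi = line_voi([3] * 7)
        rm = compute_rlm(voi, (0, 1, 0))
        assert rm.nr == 1
        assert rm.p[2, 6] == 1

    def test_ratio_features_invariant_to_doubled_counts(self):
        voi = line_voi([1, 1, 2, 2, 1, 3])
        rm = compute_rlm(voi, (0, 1, 0))
        f1 = rlm_features(rm)
        rm.p = rm.p * 2
        rm.nr = rm.nr * 2
        f2 = rlm_features(rm)
        for name in ("rlm_sre", "rlm_lre", "rlm_lgre", "rlm_hgre",
                     "rlm_srlge", "rlm_srhge", "rlm_lrlge", "rlm_lrhge"):
            assert f1[name] == pytest.approx(f2[name])

    def test_mask_gap_breaks_run(self):
        lev = np.array([1, 1, 0, 1, 1]).reshape(1, 5, 1)
        mask = lev > 0
        voi = QuantizedVOI(levels=lev, mask=mask, n_levels=1)
        rm = compute_rlm(voi, (0, 1, 0))
        assert rm.nr == 2
        assert rm.p[0, 1] == 2


# ---------------------------------------------------------------- sclgm


class TestCentroidLines:
    def test_profile_statistics_hand_values(self):
        s = profile_statistics(np.array([1, 2, 3]), n_levels=3)
        assert s["mean"] == pytest.approx(2.0)
        assert s["variance"] == pytest.approx(2 / 3)
        assert s["mad"] == pytest.approx(2 / 3)
        assert s["range"] == pytest.approx(2.0)

    def test_constant_profile_zero_variance_convention(self):
        s = profile_statistics(np.array([5, 5, 5]), n_levels=5)
        for k in ("variance", "std", "mad", "skewness", "kurtosis", "range"):
            assert s[k] == 0.0
        assert s["mean"] == 5.0 and s["energy"] == 1.0 and s["entropy"] == 0.0

    def test_spherical_voi_lines_near_equal_length(self, rng):
        n = 21
        g = np.indices((n, n, n))
        d2 = sum((gi - 10) ** 2 for gi in g)
        mask = d2 <= 8**2
        lev = np.ones((n, n, n), dtype=int)
        voi = QuantizedVOI(levels=np.where(mask, lev, 0), mask=mask, n_levels=1)
        lines = extract_centroid_lines(voi)
        steps = np.linalg.norm(build_direction_table().offsets, axis=1)
        geo = lines.line_lengths * steps  # geometric length: count x step length
        assert geo.max() - geo.min() <= 4  # within ~2 voxels of digitisation error
        assert lines.centroid == (10, 10, 10)

    def test_translation_leaves_profiles_unchanged(self, rng):
        voi = random_voi(rng, shape=(6, 6, 6))
        shift = (3, 2, 5)
        big = np.zeros((12, 13, 14), dtype=int)
        bigmask = np.zeros((12, 13, 14), dtype=bool)
        big[3:9, 2:8, 5:11] = voi.levels
        bigmask[3:9, 2:8, 5:11] = voi.mask
        moved = QuantizedVOI(levels=big, mask=bigmask, n_levels=voi.n_levels)
        a = extract_centroid_lines(voi)
        b = extract_centroid_lines(moved)
        assert tuple(np.subtract(b.centroid, a.centroid)) == shift
        for la, lb in zip(a.lines, b.lines):
            assert np.array_equal(la, lb)

    def test_sixty_one_features_stable_layout(self, rng):
        assert len(SCLGM_FEATURE_NAMES) == 61
        for _ in range(3):
            voi = random_voi(rng, shape=(7, 7, 7))
            f = sclgm_features(extract_centroid_lines(voi))
            assert tuple(f.keys()) == SCLGM_FEATURE_NAMES


# ---------------------------------------------------------------- full vector


class TestFullDescriptor:
    def test_layout_77_grouped_61_5_11(self, rng):
        voi = random_voi(rng, shape=(8, 8, 8))
        fv = extract_all(voi)
        assert len(fv) == 77
        assert len(FEATURE_NAMES) == 77
        assert sum(n.startswith("sclgm") for n in fv.names) == 61
        assert sum(n.startswith("glcm") for n in fv.names) == 5
        assert sum(n.startswith("rlm") for n in fv.names) == 11

    def test_deterministic_and_translation_invariant(self, rng):
        voi = random_voi(rng, shape=(6, 6, 6))
        fv1 = extract_all(voi)
        fv2 = extract_all(voi)
        assert np.array_equal(fv1.values, fv2.values)
        big = np.zeros((10, 11, 12), dtype=int)
        bigmask = np.zeros((10, 11, 12), dtype=bool)
        big[2:8, 3:9, 4:10] = voi.levels
        bigmask[2:8, 3:9, 4:10] = voi.mask
        moved = QuantizedVOI(levels=big, mask=bigmask, n_levels=voi.n_levels)
        assert np.allclose(extract_all(moved).values, fv1.values)

    def test_correlation_length_separates_contrast(self):
        """Coarser texture (larger correlation length) lowers mean GLCM contrast."""
        from tumortex.phantom import PhantomSpec, generate_phantom
        from tumortex.preprocess import quantize

        spec = PhantomSpec()
        idx = FEATURE_NAMES.index("glcm_contrast")
        fine, coarse = [], []
        for s in range(10):
            for label, acc in ((-1, fine), (+1, coarse)):  # -1: corr_len 1, +1: 2.5
                lv = generate_phantom(spec, label, seed=100 + s)
                acc.append(extract_all(quantize(lv.volume, lv.mask, 16)).values[idx])
        assert np.mean(fine) > np.mean(coarse)
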