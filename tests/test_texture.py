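"""Texture matrices against exhaustive brute-force oracles on small volumes."""

from collections import deque

import numpy as np
import pytest

from deltarad.texture import (
    DIRECTIONS,
    NEIGHBOR_OFFSETS,
    glcm_features,
    glcm_matrices,
    gldzm_matrix,
    glrlm_matrices,
    glszm_features,
    glszm_matrix,
    ngldm_matrix,
    ngtdm_table,
    zone_table,
)
from deltarad.volumes import DiscretizedVolume, SegmentationMask, VolumeGrid, discretize


def make_disc(levels: np.ndarray, n_bins: int | None = None) -> DiscretizedVolume:
    levels = np.asarray(levels, dtype=np.int64)
    mask = levels > 0
    nb = int(levels.max()) if n_bins is None else n_bins
    return DiscretizedVolume(levels, nb, 1.0, 0.0, float(nb), mask)


# ---------------------------------------------------------------------------
# brute-force oracles


def glcm_oracle(levels, ng):
    """Co-occurrence by explicit enumeration of every voxel pair."""
    out = np.zeros((13, ng, ng), dtype=int)
    shape = levels.shape
    for k, d in enumerate(DIRECTIONS):
        for idx in np.ndindex(shape):
            a = levels[idx]
            nb = tuple(i + o for i, o in zip(idx, d))
            if a > 0 and all(0 <= n < s for n, s in zip(nb, shape)):
                b = levels[nb]
                if b > 0:
                    out[k, a - 1, b - 1] += 1
                    out[k, b - 1, a - 1] += 1
    return out


def glszm_oracle(levels):
    """Zones by breadth-first flood fill with 26-connectivity."""
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    zones = []
    for start in np.ndindex(shape):
        if levels[start] <= 0 or seen[start]:
            continue
        g = levels[start]
        q = deque([start])
        seen[start] = True
        size = 0
        while q:
            cur = q.popleft()
            size += 1
            for off in NEIGHBOR_OFFSETS:
                nb = tuple(c + o for c, o in zip(cur, off))
                if (
                    all(0 <= n < s for n, s in zip(nb, shape))
                    and not seen[nb]
                    and levels[nb] == g
                ):
                    seen[nb] = True
                    q.append(nb)
        zones.append((int(g), size))
    return sorted(zones)


def glrlm_oracle(levels, ng, lmax):
    """Run lengths by walking every lattice line voxel-by-voxel."""
    shape = levels.shape
    out = []
    for d in DIRECTIONS:
        m = np.zeros((ng, lmax), dtype=int)
        for idx in np.ndindex(shape):
            prev = tuple(i - o for i, o in zip(idx, d))
            if all(0 <= p < s for p, s in zip(prev, shape)):
                continue  # not a line start
            # walk the line
            cur = idx
            run_val, run_len = 0, 0
            while all(0 <= c < s for c, s in zip(cur, shape)):
                v = levels[cur]
                if v == run_val:
                    run_len += 1
                else:
                    if run_val > 0:
                        m[run_val - 1, run_len - 1] += 1
                    run_val, run_len = v, 1
                cur = tuple(c + o for c, o in zip(cur, d))
            if run_val > 0:
                m[run_val - 1, run_len - 1] += 1
        out.append(m)
    return out


def ngldm_oracle(levels, ng):
    shape = levels.shape
    m = np.zeros((ng, 27), dtype=int)
    for idx in np.ndindex(shape):
        v = levels[idx]
        if v <= 0:
            continue
        k = 0
        for off in NEIGHBOR_OFFSETS:
            nb = tuple(i + o for i, o in zip(idx, off))
            if all(0 <= n < s for n, s in zip(nb, shape)) and levels[nb] == v:
                k += 1
        m[v - 1, k] += 1
    return m


# ---------------------------------------------------------------------------


class TestGLCM:
    def test_worked_2x2_block_matches_pair_enumeration(self):
        levels = np.array([[[1, 2], [1, 2]]]).reshape(2, 2, 1)
        disc = make_disc(levels, n_bins=2)
        merged = glcm_matrices(disc).sum(axis=0)
        np.testing.assert_array_equal(merged, glcm_oracle(levels, 2).sum(axis=0))

    def test_random_volumes_match_oracle_exactly(self, rng):
        for _ in range(3):
            levels = rng.integers(0, 5, size=(6, 5, 4))
            disc = make_disc(levels, n_bins=4)
            np.testing.assert_array_equal(glcm_matrices(disc), glcm_oracle(levels, 4))

    def test_checkerboard_contrast_matches_oracle(self):
        g = np.indices((4, 4, 4)).sum(axis=0) % 2 + 1
        disc = make_disc(g)
        np.testing.assert_array_equal(glcm_matrices(disc), glcm_oracle(g, 2))
        feats = glcm_features(disc, mode="merged")
        assert feats["contrast"] > 0

    def test_uniform_region_degenerate_conventions(self):
        disc = make_disc(np.ones((4, 4, 4)))
        for mode in ("averaged", "merged"):
            f = glcm_features(disc, mode)
            assert f["contrast"] == 0
            assert f["inv_diff"] == 1 and f["inv_diff_mom"] == 1
            assert f["MCC"] == 1
            assert f["energy"] == 1 and f["joint_entropy"] == 0

    def test_single_voxel_rejected(self):
        lv = np.zeros((3, 3, 3), dtype=int)
        lv[1, 1, 1] = 1
        with pytest.raises(ValueError, match="2 in-mask"):
            glcm_features(make_disc(lv))


class TestGLRLM:
    def test_random_volume_matches_line_walk_oracle(self, rng):
        levels = rng.integers(0, 4, size=(5, 4, 6))
        disc = make_disc(levels, n_bins=3)
        got = glrlm_matrices(disc)
        lmax = max(levels.shape)
        expected = glrlm_oracle(levels, 3, lmax)
        for g, e in zip(got, expected):
            np.testing.assert_array_equal(g[:, : e.shape[1]], e)


class TestZones:
    def test_single_zone_nonuniformity_is_one(self):
        disc = make_disc(np.ones((3, 3, 3)))
        assert glszm_features(disc)["GLnonuniformity_norm"] == pytest.approx(1.0)

    def test_two_disjoint_zones_different_levels(self):
        lv = np.zeros((5, 5, 5), dtype=int)
        lv[0, 0, 0] = 1
        lv[4, 4, 4] = 2
        # (1^2 + 1^2) / 2^2
        assert glszm_features(make_disc(lv))["GLnonuniformity_norm"] == pytest.approx(0.5)

    def test_random_zone_table_matches_flood_fill_oracle(self, rng):
        for _ in range(3):
            levels = rng.integers(0, 4, size=(8, 8, 8))
            disc = make_disc(levels, n_bins=3)
            lv, sz, _ = zone_table(disc)
            got = sorted(zip(lv.tolist(), sz.tolist()))
            assert got == glszm_oracle(levels)

    def test_glszm_matrix_from_zone_counts(self, rng):
        levels = rng.integers(1, 3, size=(4, 4, 4))
        disc = make_disc(levels, n_bins=2)
        m = glszm_matrix(disc)
        zones = glszm_oracle(levels)
        assert m.sum() == len(zones)

    def test_gldzm_border_zone_distance_one(self):
        lv = np.ones((3, 3, 3), dtype=int)
        lv[1, 1, 1] = 2
        m = gldzm_matrix(make_disc(lv))
        # the level-2 zone is one voxel at the center: city-block distance 2
        assert m[1, 1] == 1
        # the level-1 shell touches the ROI border: distance 1
        assert m[0, 0] == 1


class TestNeighborhoodFamilies:
    def test_ngldm_matches_neighbor_count_oracle(self, rng):
        levels = rng.integers(0, 4, size=(6, 6, 6))
        disc = make_disc(levels, n_bins=3)
        np.testing.assert_array_equal(ngldm_matrix(disc), ngldm_oracle(levels, 3))

    def test_ngtdm_uniform_volume(self):
        n_i, s_i, n = ngtdm_table(make_disc(np.ones((4, 4, 4))))
        assert n == 64
        assert s_i[0] == pytest.approx(0.0)

    def test_ngtdm_two_level_hand_case(self):
        # 2x1x1 volume: each voxel's only neighbor has the other level
        lv = np.array([1, 2]).reshape(2, 1, 1)
        n_i, s_i, n = ngtdm_table(make_disc(lv))
        assert n == 2
        np.testing.assert_allclose(s_i, [1.0, 1.0])


class TestFullTextureOnCT:
    def test_discretized_phantom_texture_finite(self, rng):
        vals = rng.normal(-600, 150, (10, 10, 10))
        vol = VolumeGrid(vals, (1, 1, 1))
        m = np.zeros((10, 10, 10))
        m[1:9, 1:9, 1:9] = 1
        disc = discretize(vol, SegmentationMask(m, (1, 1, 1)))
        for mode in ("averaged", "merged"):
            f = glcm_features(disc, mode)
            assert all(np.isfinite(v) for v in f.values())
            assert 0 <= f["MCC"] <= 1
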