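"""Wishart edge statistic, directional windows, NMS and temporal fusion."""

import numpy as np
import pytest

import polsarseg as ps
from polsarseg.edges import DIRECTIONS

from conftest import random_pd_matrix


def stats(n, m):
    return ps.RegionStats(n, np.asarray(m, dtype=complex))


class TestWishartDistance:
    def test_identical_stats_give_zero(self, rng):
        m = random_pd_matrix(rng)
        assert ps.wishart_distance(stats(17, m), stats(17, m)) == 0.0

    def test_hand_computed_value(self):
        # halves I and 2I with 10 samples each: pooled 1.5I,
        # D = 60 ln 1.5 - 30 ln 2 = 30 ln 1.125
        d = ps.wishart_distance(stats(10, np.eye(3)), stats(10, 2 * np.eye(3)))
        assert d == pytest.approx(30 * np.log(1.125), abs=1e-9)

    def test_symmetric_exactly(self, rng):
        a = stats(7, random_pd_matrix(rng))
        b = stats(12, random_pd_matrix(rng))
        assert ps.wishart_distance(a, b) == ps.wishart_distance(b, a)

    def test_nonnegative_on_random_pd_pairs(self, rng):
        for _ in range(1000):
            a = stats(rng.integers(1, 40), random_pd_matrix(rng, scale=rng.uniform(0.1, 10)))
            b = stats(rng.integers(1, 40), random_pd_matrix(rng, scale=rng.uniform(0.1, 10)))
            assert ps.wishart_distance(a, b) >= 0.0

    def test_grows_with_dissimilarity(self):
        a = stats(10, np.eye(3))
        d1 = ps.wishart_distance(a, stats(10, 2 * np.eye(3)))
        d2 = ps.wishart_distance(a, stats(10, 8 * np.eye(3)))
        assert d2 > d1 > 0


class TestDirectionalHalves:
    def test_horizontal_window3(self):
        neg, pos = ps.directional_halves(3, 0)
        assert {tuple(o) for o in neg} == {(-1, -1), (-1, 0), (-1, 1)}
        assert {tuple(o) for o in pos} == {(1, -1), (1, 0), (1, 1)}

    def test_diagonal_window3(self):
        neg, pos = ps.directional_halves(3, 45)
        assert {tuple(o) for o in neg} == {(-1, -1), (-1, 0), (0, -1)}
        assert {tuple(o) for o in pos} == {(1, 1), (1, 0), (0, 1)}

    @pytest.mark.parametrize("w", [3, 5, 7, 9])
    @pytest.mark.parametrize("theta", DIRECTIONS)
    def test_halves_disjoint_equal_mirrored(self, w, theta):
        neg, pos = ps.directional_halves(w, theta)
        sn = {tuple(o) for o in neg}
        sp = {tuple(o) for o in pos}
        assert len(sn) == len(sp) == w * (w - 1) // 2
        assert not sn & sp
        assert (0, 0) not in sn | sp
        assert {(-r, -c) for r, c in sn} == sp  # mirror through the split line

    @pytest.mark.parametrize("w", [2, 1, 4])
    def test_bad_window_rejected(self, w):
        with pytest.raises(ValueError):
            ps.directional_halves(w, 0)


def vertical_step_image(h=64, w=64, ratio=4.0):
    data = np.tile(np.eye(3, dtype=complex), (h, w, 1, 1))
    data[:, w // 2:] *= ratio
    return ps.CovarianceImage(data, looks=4)


class TestDetectEdges:
    def test_homogeneous_image_zero_strength(self):
        data = np.tile(2 * np.eye(3, dtype=complex), (12, 12, 1, 1))
        em = ps.detect_edges(ps.CovarianceImage(data), window=5)
        assert np.allclose(em.strength, 0.0, atol=1e-8)

    def test_noise_free_vertical_step_peaks_at_boundary(self):
        em = ps.detect_edges(vertical_step_image(), window=7)
        col_profile = em.strength.max(axis=0)
        peaks = np.nonzero(col_profile == col_profile.max())[0]
        assert set(peaks) <= {31, 32}
        assert (em.direction_deg[:, peaks] == 90).all()

    def test_strength_invariant_to_global_scaling(self):
        img = vertical_step_image(h=16, w=16)
        a = ps.detect_edges(img, window=5)
        b = ps.detect_edges(
            ps.CovarianceImage(1234.5 * img.data, looks=4), window=5
        )
        assert np.allclose(a.strength, b.strength, rtol=1e-6, atol=1e-6)

    def test_speckled_step_boundary_exceeds_interior(self):
        # Monte-Carlo: mean strength on the step beats the field 5+ cols away
        boundary, interior = [], []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            spec = ps.SceneSpec(
                parcel_map=ps.grid_parcels(16, 24, 1, 2),
                class_of_parcel={1: 1, 2: 2},
                sigma={(1, 0): np.eye(3), (2, 0): 4 * np.eye(3)},
                looks=4, n_dates=1, seed=seed,
            )
            (img,), _ = ps.generate_timeseries(spec)
            em = ps.detect_edges(img, window=5)
            boundary.append(em.strength[:, 11:13].mean())
            interior.append(em.strength[:, 4:6].mean())
        assert np.mean(boundary) > np.mean(interior)

    def test_oversized_window_rejected(self):
        with pytest.raises(ValueError):
            ps.detect_edges(vertical_step_image(h=8, w=8), window=17)


class TestOrientedNms:
    def _edgemap(self, strength, theta):
        s = np.asarray(strength, dtype=float)
        return ps.EdgeMap(s, np.full(s.shape, theta, dtype=np.int16))

    def test_isolated_ridge_unchanged(self):
        s = np.zeros((5, 5))
        s[2] = 7.0  # single-pixel-wide horizontal ridge
        out = ps.oriented_nms(self._edgemap(s, 0))
        assert np.array_equal(out.strength, s)

    def test_vertical_stack_keeps_middle(self):
        s = np.zeros((3, 3))
        s[:, 1] = [1.0, 5.0, 2.0]
        out = ps.oriented_nms(self._edgemap(s, 0))  # 0 deg: compare up/down
        assert out.strength[1, 1] == 5.0
        assert out.strength[0, 1] == 0.0 and out.strength[2, 1] == 0.0

    def test_plateau_fully_kept(self):
        s = np.full((4, 4), 3.0)
        for theta in DIRECTIONS:
            out = ps.oriented_nms(self._edgemap(s, theta))
            assert np.array_equal(out.strength, s)

    def test_never_increases_strength(self, rng):
        s = rng.random((8, 8))
        theta = rng.choice(DIRECTIONS, size=(8, 8)).astype(np.int16)
        out = ps.oriented_nms(ps.EdgeMap(s, theta))
        assert (out.strength <= s).all()


class TestFuseEdges:
    def _em(self, s, theta=0):
        s = np.asarray(s, dtype=float)
        return ps.EdgeMap(s, np.full(s.shape, theta, dtype=np.int16))

    def test_single_map_identity(self):
        em = self._em([[1.0, 2.0]])
        out = ps.fuse_edges([em])
        assert np.array_equal(out.strength, em.strength)

    def test_pointwise_maximum_and_winning_date_direction(self):
        a = self._em([[2.0]], theta=0)
        b = self._em([[5.0]], theta=90)
        out = ps.fuse_edges([a, b])
        assert out.strength[0, 0] == 5.0 and out.direction_deg[0, 0] == 90
        tie = ps.fuse_edges([self._em([[3.0]], 45), self._em([[3.0]], 135)])
        assert tie.direction_deg[0, 0] == 45  # earliest date wins ties

    def test_fused_dominates_inputs_on_canned_scene(self, canned_stages,
                                                    canned_result):
        stages, _ = canned_stages
        fused = canned_result.fused
        for _, em in stages:
            assert (fused.strength >= em.strength - 1e-12).all()

    def test_shape_mismatch_names_date_index(self):
        with pytest.raises(ValueError, match="date index 1"):
            ps.fuse_edges([self._em([[1.0]]), self._em([[1.0, 2.0]])])
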