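"""Mean-shift filtering, mode labelling and minimum-region enforcement."""

import numpy as np
import pytest

import polsarseg as ps


def brute_force_meanshift(feats, hs, hr, max_iter=200, tol=1e-6):
    """Independent O(N^2) joint-space mean-shift: no truncation, all samples.

    Gaussian profile exp(-u/2) on the bandwidth-normalised squared norms of
    the spatial and range blocks separately; iterates every pixel until the
    joint displacement falls below tol.
    """
    h, w, _ = feats.shape
    rows, cols = np.mgrid[0:h, 0:w]
    xs = np.stack([rows.ravel(), cols.ravel()], axis=1).astype(float)
    xr = feats.reshape(-1, 3).astype(float)
    out = []
    for i in range(len(xs)):
        s, r = xs[i].copy(), xr[i].copy()
        for _ in range(max_iter):
            ds2 = np.sum((xs - s) ** 2, axis=1) / hs**2
            dr2 = np.sum((xr - r) ** 2, axis=1) / hr**2
            wgt = np.exp(-0.5 * (ds2 + dr2))
            new_s = (wgt[:, None] * xs).sum(0) / wgt.sum()
            new_r = (wgt[:, None] * xr).sum(0) / wgt.sum()
            disp2 = (np.sum((new_s - s) ** 2) / hs**2
                     + np.sum((new_r - r) ** 2) / hr**2)
            s, r = new_s, new_r
            if disp2 < tol**2:
                break
        out.append(np.concatenate([s, r]))
    return np.array(out).reshape(h, w, 5)


class TestMeanShiftFilter:
    def test_constant_image_is_fixed_point(self):
        img = ps.PauliImage(np.full((4, 5, 3), 2.5))
        cfg = ps.MeanShiftConfig(hs=2, hr=1, max_iter=50)
        out, joint = ps.meanshift_filter(img, cfg)
        assert np.allclose(out.features, 2.5, atol=1e-9)
        # spatial part converges to the local window centroid but the range
        # part never moves off the constant value
        assert np.allclose(joint[..., 2:], 2.5, atol=1e-9)

    def test_single_pixel_unchanged(self):
        img = ps.PauliImage(np.array([[[1.0, 2.0, 3.0]]]))
        out, _ = ps.meanshift_filter(img, ps.MeanShiftConfig(hs=3, hr=1))
        assert np.allclose(out.features, [[1.0, 2.0, 3.0]])

    def test_two_cluster_toy_matches_brute_force(self):
        # 4x4 image, left half features 0, right half 10; hs spans the grid
        feats = np.zeros((4, 4, 3))
        feats[:, 2:] = 10.0
        cfg = ps.MeanShiftConfig(hs=10, hr=1, max_iter=200, tol=1e-6)
        _, joint = ps.meanshift_filter(ps.PauliImage(feats), cfg)
        oracle = brute_force_meanshift(feats, hs=10, hr=1)
        assert np.allclose(joint, oracle, atol=1e-3)
        # each pixel converges to (within tolerance of) its own cluster mean
        assert np.allclose(joint[:, :2, 2:], 0.0, atol=1e-3)
        assert np.allclose(joint[:, 2:, 2:], 10.0, atol=1e-3)

    def test_within_cluster_variance_never_increases(self):
        rng = np.random.default_rng(0)
        feats = np.zeros((4, 8, 3))
        feats[:, 4:] = 10.0
        feats += rng.normal(0, 0.3, feats.shape)
        cfg = ps.MeanShiftConfig(hs=10, hr=1, max_iter=100)
        out, _ = ps.meanshift_filter(ps.PauliImage(feats), cfg)
        for sl in (np.s_[:, :4], np.s_[:, 4:]):
            before = feats[sl].reshape(-1, 3).var(axis=0).sum()
            after = out.features[sl].reshape(-1, 3).var(axis=0).sum()
            assert after <= before + 1e-12

    def test_non_finite_features_rejected(self):
        feats = np.zeros((2, 2, 3))
        feats[1, 1, 0] = np.nan
        with pytest.raises(Exception, match=r"\(1, 1\)"):
            ps.meanshift_filter(ps.PauliImage(feats), ps.MeanShiftConfig(hs=2, hr=1))


class TestLabelModes:
    def _joint(self, spatial, ranges):
        h, w = np.shape(spatial)[:2]
        return np.concatenate(
            [np.asarray(spatial, float), np.asarray(ranges, float)], axis=-1
        )

    def test_single_mode_single_region(self):
        joint = np.zeros((3, 3, 5))
        lbl = ps.label_modes(joint, ps.MeanShiftConfig(hs=4, hr=1))
        assert lbl.n_regions == 1

    def test_two_range_clusters_two_regions(self):
        joint = np.zeros((2, 4, 5))
        joint[..., 0] = 0.5  # same spatial mode
        joint[:, 2:, 2:] = 10.0  # far apart in range
        lbl = ps.label_modes(joint, ps.MeanShiftConfig(hs=10, hr=1))
        lbl.validate()
        assert lbl.n_regions == 2

    def test_same_mode_disjoint_blobs_split(self):
        # range-identical convergence points but two spatially distant blobs
        # whose convergence points exceed hs/2: 1 column gap, all same range
        joint = np.zeros((1, 5, 5))
        joint[0, :, 1] = [0, 0, 2.4, 4.8, 4.8]  # converged col positions
        joint[0, 2, 2:] = 99.0  # middle pixel is its own range mode
        lbl = ps.label_modes(joint, ps.MeanShiftConfig(hs=2, hr=1))
        assert lbl.n_regions == 3  # left pair, separator, right pair


class TestEnforceMinRegion:
    def test_all_regions_large_enough_unchanged(self):
        labels = np.repeat([[1, 2]], 4, axis=0).repeat(2, axis=1)
        img = ps.PauliImage(np.zeros(labels.shape + (3,)))
        out = ps.enforce_min_region(ps.LabelMap(labels), img, 4)
        assert np.array_equal(out.labels, labels)

    def test_small_region_merges_to_nearest_mean(self):
        labels = np.array([[1, 1, 2, 3, 3]])
        feats = np.zeros((1, 5, 3))
        feats[0, :2] = 0.0    # region 1 mean (0,0,0)
        feats[0, 2] = 8.0     # region 2 mean (8,8,8) -> closer to region 3
        feats[0, 3:] = 9.0    # region 3 mean (9,9,9)
        out = ps.enforce_min_region(
            ps.LabelMap(labels), ps.PauliImage(feats), 2
        )
        assert out.n_regions == 2
        assert out.labels[0, 2] == out.labels[0, 3]  # merged rightward

    def test_unit_minimum_is_identity(self):
        labels = np.array([[1, 2], [3, 4]])
        img = ps.PauliImage(np.zeros((2, 2, 3)))
        out = ps.enforce_min_region(ps.LabelMap(labels), img, 1)
        assert np.array_equal(out.labels, labels)

    def test_whole_image_smaller_than_m_collapses_to_one(self):
        labels = np.array([[1, 2]])
        img = ps.PauliImage(np.zeros((1, 2, 3)))
        out = ps.enforce_min_region(ps.LabelMap(labels), img, 10)
        assert out.n_regions == 1

    def test_minimum_size_respected(self, rng):
        labels = rng.integers(1, 6, size=(12, 12))
        from skimage import measure

        labels = measure.label(labels, connectivity=1)
        img = ps.PauliImage(rng.random((12, 12, 3)))
        out = ps.enforce_min_region(ps.LabelMap(labels), img, 5)
        out.validate()
        sizes = np.bincount(out.labels.ravel())[1:]
        assert (sizes >= min(5, labels.size)).all()


class TestOversegmentationContract:
    def test_every_parcel_has_majority_region(self, canned_stages, canned_scene):
        """Over-segmentation, not under-segmentation: each ground-truth parcel
        must own at least one region (majority vote), on every date."""
        stages, _ = canned_stages
        _, _, truth = canned_scene
        for lbl, _ in stages:
            lbl.validate()
            owners = set()
            for rid in range(1, lbl.n_regions + 1):
                parcels = truth.labels[lbl.labels == rid]
                owners.add(int(np.bincount(parcels).argmax()))
            assert owners >= set(range(1, truth.n_regions + 1))

    def test_region_count_exceeds_parcel_count(self, canned_stages, canned_scene):
        stages, _ = canned_stages
        _, _, truth = canned_scene
        for lbl, _ in stages:
            assert lbl.n_regions > truth.n_regions
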