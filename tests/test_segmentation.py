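"""Tests for per-slice segmentation, components and fiducial separation."""

import numpy as np
import pytest

from mpiquant.phantom import PhantomConfig, IronSource, render_scan
from mpiquant.scan_io import FiducialSpec
from mpiquant.segmentation import (
    Component,
    ComponentSet,
    FiducialMatchError,
    assign_fiducials,
    estimate_signal_floor,
    label_components,
    segment_slice,
    segment_volume,
)


def _fid(id_, center, radius=5.0):
    return FiducialSpec(
        id=id_, expected_center=center, concentration_fraction=0.4,
        stock_iron_mg_per_ml=5.5, volume_ul=1.0, search_radius=radius,
    )


class TestSegmentSlice:
    def test_separable_blob_recovered_exactly(self):
        img = np.zeros((32, 32))
        img[10:14, 10:14] = 1000.0
        seg = segment_slice(img, k=2, rng=0)
        assert np.array_equal(seg.roi_mask, img > 0)
        assert seg.roi_pixel_sum == pytest.approx(16 * 1000.0)

    def test_all_zero_slice_empty_mask(self):
        seg = segment_slice(np.zeros((16, 16)), k=4, rng=0)
        assert not seg.roi_mask.any()
        assert seg.roi_pixel_sum == 0.0

    def test_four_tiers_top1_equals_midpoint_threshold(self):
        """With four exact intensity tiers and k=4, the ROI is the
        brightest tier — identical to thresholding at the midpoint of the
        top two centroids."""
        rng = np.random.default_rng(0)
        img = rng.choice([0.0, 5.0, 20.0, 100.0], size=(32, 32), p=[0.7, 0.15, 0.1, 0.05])
        img[0, 0] = 100.0  # ensure the bright tier is present
        seg = segment_slice(img, k=4, rng=1)
        c = seg.cluster_model.centroids
        assert c.tolist() == [0.0, 5.0, 20.0, 100.0]
        assert np.array_equal(seg.roi_mask, img > (c[2] + c[3]) / 2)
        assert seg.roi_pixel_sum == pytest.approx(img[img == 100.0].sum())

    def test_fewer_distinct_values_falls_back(self):
        img = np.zeros((8, 8))
        img[0, 0] = 7.0
        seg = segment_slice(img, k=4, rng=0)
        assert seg.k_fallback and seg.k_used == 2
        assert seg.roi_mask.sum() == 1

    def test_topm_policy_selects_two_tiers(self):
        rng = np.random.default_rng(2)
        img = rng.choice([0.0, 10.0, 100.0], size=(24, 24), p=[0.8, 0.12, 0.08])
        img[0, 0], img[0, 1] = 10.0, 100.0
        seg = segment_slice(img, k=3, selection_policy="topm:2", rng=0)
        assert np.array_equal(seg.roi_mask, img > 0)

    def test_mask_invariant_under_positive_affine_rescaling(self):
        rng = np.random.default_rng(3)
        img = rng.choice([0.0, 4.0, 30.0, 90.0], size=(20, 20))
        a = segment_slice(img, k=4, rng=5)
        b = segment_slice(2.5 * img + 7.0, k=4, rng=5)
        assert np.array_equal(a.roi_mask, b.roi_mask)

    def test_signal_floor_gates_dim_slice(self):
        img = np.zeros((16, 16))
        img[4, 4] = 3.0
        seg = segment_slice(img, k=2, rng=0, min_signal=10.0)
        assert seg.gated and not seg.roi_mask.any()


class TestSegmentVolume:
    def test_one_segmentation_per_slice(self):
        cfg = PhantomConfig(sources=[IronSource((18, 32, 32), 1.0, "graft")],
                            noise_additive_sd=0.0, noise_multiplicative_cv=0.0)
        scan, _ = render_scan(cfg)
        seg = segment_volume(scan, k=4, seed=0)
        assert len(seg.slices) == 36
        assert seg.roi_mask.shape == scan.voxels.shape

    def test_zero_volume_all_empty(self):
        seg = segment_volume(np.zeros((5, 8, 8)), k=4, seed=0)
        assert not seg.roi_mask.any()

    def test_identical_slices_get_identical_masks(self):
        rng = np.random.default_rng(1)
        sl = rng.choice([0.0, 10.0, 200.0], size=(16, 16), p=[0.8, 0.15, 0.05])
        vol = np.stack([sl] * 4)
        seg = segment_volume(vol, k=3, seed=7, signal_floor=0.0)
        for s in seg.slices[1:]:
            assert np.array_equal(s.roi_mask, seg.slices[0].roi_mask)

    def test_per_slice_sums_consistent_with_3d_mask(self):
        cfg = PhantomConfig(sources=[IronSource((18, 32, 32), 1.0, "graft")], rng_seed=3)
        scan, _ = render_scan(cfg)
        seg = segment_volume(scan, seed=1)
        total = sum(s.roi_pixel_sum for s in seg.slices)
        assert total == pytest.approx(scan.voxels[seg.roi_mask].sum())

    def test_determinism(self):
        cfg = PhantomConfig(sources=[IronSource((10, 20, 20), 1.0, "graft")], rng_seed=5)
        scan, _ = render_scan(cfg)
        a = segment_volume(scan, seed=3)
        b = segment_volume(scan, seed=3)
        assert np.array_equal(a.roi_mask, b.roi_mask)


class TestSignalFloor:
    def test_zero_for_mostly_zero_volume(self):
        vol = np.zeros((6, 10, 10))
        vol[3, 5, 5] = 100.0
        assert estimate_signal_floor(vol) == 0.0

    def test_scales_with_noise_sd(self):
        rng = np.random.default_rng(0)
        vol = np.clip(rng.normal(0, 2.0, size=(20, 50, 50)), 0, None)
        floor = estimate_signal_floor(vol)
        assert 6 * 2.0 * 0.7 < floor < 6 * 2.0 * 1.3


class TestComponents:
    def test_two_separated_blobs(self):
        mask = np.zeros((6, 10, 10), bool)
        mask[1, 1:3, 1:3] = True
        mask[4, 7:9, 7:9] = True
        cs = label_components(mask)
        assert len(cs.components) == 2

    def test_empty_mask(self):
        assert label_components(np.zeros((3, 3, 3), bool)).components == []

    def test_diagonal_touch_depends_on_connectivity(self):
        mask = np.zeros((4, 4, 4), bool)
        mask[1, 1, 1] = mask[2, 2, 2] = True
        assert len(label_components(mask, connectivity=26).components) == 1
        assert len(label_components(mask, connectivity=6).components) == 2

    def test_pixel_sums_use_intensity(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[0, 0, 0] = mask[0, 0, 1] = True
        intensity = np.arange(27, dtype=float).reshape(3, 3, 3)
        cs = label_components(mask, intensity=intensity)
        assert cs.components[0].pixel_sum == pytest.approx(intensity[0, 0, 0] + intensity[0, 0, 1])

    def test_min_size_filters_specks(self):
        mask = np.zeros((6, 10, 10), bool)
        mask[1, 1:4, 1:4] = True   # 9 voxels
        mask[4, 8, 8] = True       # single speck
        cs = label_components(mask, min_size=5)
        assert len(cs.components) == 1
        assert cs.components[0].n_voxels == 9

    def test_components_partition_mask(self):
        rng = np.random.default_rng(2)
        mask = rng.random((5, 12, 12)) > 0.85
        cs = label_components(mask)
        assert sum(c.n_voxels for c in cs.components) == int(mask.sum())
        assert np.array_equal(cs.labels > 0, mask)


class TestAssignFiducials:
    def _component(self, label, centroid, pixel_sum=100.0):
        return Component(label=label, n_voxels=10, centroid=centroid,
                         pixel_sum=pixel_sum, bbox=((0, 1), (0, 1), (0, 1)))

    def test_three_fiducials_plus_graft(self):
        comps = ComponentSet(
            labels=np.zeros((1, 1, 1), int),
            components=[
                self._component(1, (5.0, 8.0, 16.0)),
                self._component(2, (13.0, 8.0, 32.0)),
                self._component(3, (21.0, 8.0, 48.0)),
                self._component(4, (29.0, 40.0, 32.0)),
            ],
            connectivity=26,
        )
        fids = [_fid("a", (5, 8, 16)), _fid("b", (13, 8, 32)), _fid("c", (21, 8, 48))]
        fid_map, graft = assign_fiducials(comps, fids)
        assert {f: c.label for f, c in fid_map.items()} == {"a": 1, "b": 2, "c": 3}
        assert [c.label for c in graft] == [4]

    def test_nearer_component_wins_within_radius(self):
        comps = ComponentSet(
            labels=np.zeros((1, 1, 1), int),
            components=[
                self._component(1, (10.0, 10.0, 10.0)),  # true fiducial, d=1
                self._component(2, (10.0, 10.0, 14.0)),  # graft inside radius, d=3
            ],
            connectivity=26,
        )
        fid_map, graft = assign_fiducials(comps, [_fid("a", (10, 10, 11), radius=5)])
        assert fid_map["a"].label == 1
        assert [c.label for c in graft] == [2]

    def test_missing_fiducial_raises(self):
        comps = ComponentSet(labels=np.zeros((1, 1, 1), int), components=[], connectivity=26)
        with pytest.raises(FiducialMatchError, match="a"):
            assign_fiducials(comps, [_fid("a", (5, 5, 5))])


def test_noise_free_scan_segments_all_sources(noise_free_scan, fiducials):
    """On a noise-free phantom every source produces one component and the
    fiducial map is complete."""
    from mpiquant.segmentation import separate_fiducials

    scan, truth = noise_free_scan
    seg = segment_volume(scan, seed=0)
    seg = separate_fiducials(seg, scan, fiducials, min_component_size=5)
    assert set(seg.fiducial_components) == {f.id for f in fiducials}
    assert len(seg.graft_components) == 1
    # graft pixel sums live only on slices near the graft z-plane
    nz = np.nonzero(seg.per_slice_graft_sums)[0]
    assert 25 <= nz.min() and nz.max() <= 33
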