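"""Unit tests of the morphological segmentation and descriptor operations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from morphofun import morpho
from morphofun.morpho import (
    FieldImage,
    build_search_region,
    call_synapses,
    classify_nuclei,
    compute_morphological_descriptors,
    count_nodes,
    count_synapses,
    detect_spots,
    max_project,
    pearson_colocalization,
    segment_dendrites,
    segment_field,
    segment_nuclei,
    select_sharpest_slice,
    skeleton_length,
)


# ---------------------------------------------------------------------------
# projection and slice selection
# ---------------------------------------------------------------------------

class TestProjection:
    def test_single_slice_identity(self):
        img = np.arange(12.0).reshape(1, 3, 4)
        np.testing.assert_array_equal(max_project(img), img[0])

    def test_elementwise_maximum(self):
        stack = np.array([[[0, 5]], [[3, 1]]], dtype=float)
        np.testing.assert_array_equal(max_project(stack), [[3, 5]])

    def test_matches_loop_oracle(self, rng):
        stack = rng.normal(size=(3, 16, 16))
        expect = np.empty((16, 16))
        for i in range(16):
            for j in range(16):
                expect[i, j] = max(stack[z, i, j] for z in range(3))
        np.testing.assert_allclose(max_project(stack), expect)

    def test_empty_stack_errors(self):
        with pytest.raises(ValueError):
            max_project(np.empty((0, 4, 4)))

    def test_sharpest_slice_picks_high_contrast(self, rng):
        stack = np.ones((4, 16, 16))
        stack[2] = rng.normal(scale=5.0, size=(16, 16))
        assert select_sharpest_slice(stack) == 2

    def test_sharpest_slice_single_and_tie(self):
        assert select_sharpest_slice(np.zeros((1, 8, 8))) == 0
        assert select_sharpest_slice(np.zeros((3, 8, 8))) == 0  # ties -> lowest

    def test_sharpest_slice_matches_sd_oracle(self, rng):
        stack = rng.normal(size=(5, 12, 12))
        sds = [stack[z].std() for z in range(5)]
        assert select_sharpest_slice(stack) == int(np.argmax(sds))


# ---------------------------------------------------------------------------
# nuclei
# ---------------------------------------------------------------------------

def _disc(canvas, cy, cx, r, value=100.0):
    yy, xx = np.mgrid[: canvas.shape[0], : canvas.shape[1]]
    canvas[np.hypot(yy - cy, xx - cx) <= r] = value
    return canvas


class TestNuclei:
    def test_blank_image_gives_no_labels(self):
        labels = segment_nuclei(np.zeros((64, 64)), threshold=10)
        assert labels.max() == 0

    def test_two_disjoint_discs(self):
        img = np.zeros((128, 128))
        _disc(img, 32, 32, 14)
        _disc(img, 90, 90, 14)
        labels = segment_nuclei(img, threshold=50)
        assert labels.max() == 2

    def test_touching_discs_are_split(self):
        img = np.zeros((128, 128))
        _disc(img, 60, 48, 15)
        _disc(img, 60, 76, 15)
        labels = segment_nuclei(img, threshold=50, split_min_distance=10)
        assert labels.max() == 2

    def test_small_components_removed(self):
        img = np.zeros((64, 64))
        img[10:13, 10:13] = 100.0  # 9 px, below min area
        assert segment_nuclei(img, threshold=50, min_area_px=120).max() == 0

    def test_large_flat_nucleus_is_non_neuronal(self):
        img = np.zeros((128, 128))
        _disc(img, 64, 64, 30)  # area ~ 2827 px ~ 63 um^2
        labels = segment_nuclei(img, threshold=50)
        recs = classify_nuclei(
            labels, np.zeros_like(labels, bool), img,
            max_area_um2=40.0, min_circularity=0.6, min_occupancy=0.0,
        )
        assert len(recs) == 1 and not recs[0].is_neuronal

    def test_small_round_nucleus_on_dendrite_is_neuronal(self):
        img = np.zeros((128, 128))
        _disc(img, 64, 64, 15)
        labels = segment_nuclei(img, threshold=50)
        dend = np.zeros((128, 128), bool)
        dend[62:66, :] = True  # dendrite crossing the soma ring
        recs = classify_nuclei(
            labels, dend, img,
            max_area_um2=40.0, min_circularity=0.6, min_occupancy=0.02,
        )
        assert len(recs) == 1 and recs[0].is_neuronal
        assert 0.0 <= recs[0].occupancy <= 1.0
        assert recs[0].circularity <= 1.05

    def test_border_nucleus_flagged(self):
        img = np.zeros((96, 96))
        _disc(img, 2, 48, 12)
        labels = segment_nuclei(img, threshold=50)
        recs = classify_nuclei(
            labels, np.zeros_like(labels, bool), img,
            max_area_um2=40.0, min_circularity=0.6, min_occupancy=0.0,
        )
        assert recs[0].touches_border


# ---------------------------------------------------------------------------
# dendrites
# ---------------------------------------------------------------------------

class TestDendrites:
    def test_blank_image(self):
        mask, skel = segment_dendrites(np.zeros((64, 64)), 50, 0.1)
        assert not mask.any()
        assert skeleton_length(skel) == 0.0

    def test_straight_ridge_length(self):
        img = np.zeros((64, 128))
        img[30:34, 10:110] = 200.0  # 100 px long horizontal ridge
        mask, skel = segment_dendrites(img, rough_threshold=100, fine_threshold=1e9)
        length_px = skeleton_length(skel, pixel_size=1.0)
        assert length_px == pytest.approx(100, rel=0.1)

    def test_skeleton_length_diagonal_weighting(self):
        sk = np.eye(10, dtype=bool)  # pure diagonal: 9 diagonal steps
        assert skeleton_length(sk, pixel_size=1.0) == pytest.approx(9 * np.sqrt(2))

    def test_straight_line_has_no_nodes(self):
        sk = np.zeros((32, 32), bool)
        sk[16, 4:28] = True
        assert count_nodes(sk) == 0

    def test_symmetric_y_has_one_node(self):
        sk = np.zeros((32, 32), bool)
        sk[16:28, 16] = True  # stem
        for i in range(10):
            sk[15 - i, 16 - i] = True
            sk[15 - i, 16 + i] = True
        assert count_nodes(sk) == 1

    def test_empty_scales_error(self):
        with pytest.raises(ValueError):
            segment_dendrites(np.zeros((32, 32)), 50, 0.1, frangi_scales=())


# ---------------------------------------------------------------------------
# search region
# ---------------------------------------------------------------------------

class TestSearchRegion:
    def test_empty_dendrite_mask(self):
        region = build_search_region(
            np.zeros((32, 32), bool), np.zeros((32, 32), bool)
        )
        assert not region.any()

    def test_region_superset_of_dendrites_without_nuclei(self, rng):
        dend = rng.random((64, 64)) > 0.9
        region = build_search_region(dend, np.zeros_like(dend))
        assert (region | dend).sum() == region.sum()

    def test_matches_pixelwise_set_oracle(self, rng):
        from skimage.morphology import dilation, disk

        dend = rng.random((48, 48)) > 0.92
        nuc = rng.random((48, 48)) > 0.95
        region = build_search_region(dend, nuc, 3, 2)
        oracle = dilation(dend, disk(3)) & ~dilation(nuc, disk(2))
        np.testing.assert_array_equal(region, oracle)


# ---------------------------------------------------------------------------
# spots and synapses
# ---------------------------------------------------------------------------

def _spot_image(sizes):
    """One horizontal run of `size` bright pixels per row, well separated."""
    img = np.zeros((len(sizes) * 10 + 10, 64))
    for i, size in enumerate(sizes):
        img[10 + i * 10, 5 : 5 + size] = 500.0
    return img


class TestSpots:
    @pytest.mark.parametrize("size,kept", [(4, False), (5, True)])
    def test_size_filter_boundary(self, size, kept):
        # bypass the DoG: use a pre-enhanced landscape via direct threshold
        img = np.zeros((32, 32))
        img[16, 5 : 5 + size] = 1000.0
        region = np.ones_like(img, bool)
        spots = detect_spots(img, region, 0.5, 3.0, spot_threshold=50.0)
        assert (spots.max() > 0) == kept

    def test_size_filter_exactness_1_to_10(self):
        """Constructed components of 1-10 px: exactly those >= 5 px survive."""
        for size in range(1, 11):
            mask = np.zeros((16, 16), bool)
            mask[8, 2 : 2 + size] = True
            labels = morpho.cc_label(mask, connectivity=2)
            ids, counts = np.unique(labels[labels > 0], return_counts=True)
            survivors = ids[counts >= 5]
            assert (len(survivors) == 1) == (size >= 5)

    def test_spots_outside_search_region_ignored(self):
        img = np.zeros((64, 64))
        img[20, 10:20] = 500.0
        region = np.zeros_like(img, bool)
        region[40:, :] = True
        assert detect_spots(img, region, 1.0, 3.0, 20.0).max() == 0

    def test_sigma_order_enforced(self):
        with pytest.raises(ValueError):
            detect_spots(np.zeros((16, 16)), np.ones((16, 16), bool), 3.0, 1.0, 10.0)


def brute_force_pairs(pre, post, min_overlap=1):
    """Double-loop pixel-intersection oracle for synapse calling."""
    out = []
    for p in np.unique(pre[pre > 0]):
        for q in np.unique(post[post > 0]):
            ov = int(((pre == p) & (post == q)).sum())
            if ov >= min_overlap:
                out.append((int(p), int(q), ov))
    return sorted(out)


class TestSynapses:
    def test_single_pixel_overlap_is_a_synapse(self):
        pre = np.zeros((16, 16), int)
        post = np.zeros((16, 16), int)
        pre[4:8, 4:8] = 1
        post[7:10, 7:10] = 1  # shares exactly (7,7)
        pairs = call_synapses(pre, post)
        assert pairs == [(1, 1, 1)]
        assert count_synapses(pairs) == 1

    def test_disjoint_masks(self):
        pre = np.zeros((16, 16), int)
        post = np.zeros((16, 16), int)
        pre[2:4, 2:4] = 1
        post[10:12, 10:12] = 1
        assert call_synapses(pre, post) == []

    def test_one_pre_two_posts_counts_once(self):
        pre = np.zeros((16, 16), int)
        post = np.zeros((16, 16), int)
        pre[4:10, 4:10] = 1
        post[4:6, 4:6] = 1
        post[8:10, 8:10] = 2
        pairs = call_synapses(pre, post)
        assert len(pairs) == 2
        assert count_synapses(pairs) == 1

    def test_matches_brute_force_on_random_masks(self, rng):
        for _ in range(25):
            pre = rng.integers(0, 4, size=(32, 32))
            post = rng.integers(0, 4, size=(32, 32))
            for mo in (1, 2, 3):
                assert sorted(call_synapses(pre, post, mo)) == brute_force_pairs(
                    pre, post, mo
                )

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        pre=hnp.arrays(np.int64, (12, 12), elements=st.integers(0, 3)),
        post=hnp.arrays(np.int64, (12, 12), elements=st.integers(0, 3)),
    )
    def test_property_oracle_equivalence(self, pre, post):
        assert sorted(call_synapses(pre, post)) == brute_force_pairs(pre, post)


class TestColocalization:
    def test_identical_images(self, rng):
        img = rng.random((32, 32))
        assert pearson_colocalization(img, img, np.ones_like(img, bool)) == pytest.approx(1.0)

    def test_negated_image(self, rng):
        img = rng.random((32, 32))
        assert pearson_colocalization(img, -img, np.ones_like(img, bool)) == pytest.approx(-1.0)

    def test_matches_covariance_formula(self, rng):
        x, y = rng.random((2, 24, 24))
        region = rng.random((24, 24)) > 0.3
        r = pearson_colocalization(x, y, region)
        xv, yv = x[region], y[region]
        expect = ((xv - xv.mean()) * (yv - yv.mean())).mean() / (xv.std() * yv.std())
        assert r == pytest.approx(expect)

    def test_constant_channel_gives_zero(self):
        assert pearson_colocalization(
            np.ones((8, 8)), np.random.default_rng(0).random((8, 8)), np.ones((8, 8), bool)
        ) == 0.0

    def test_empty_region_errors(self):
        with pytest.raises(ValueError):
            pearson_colocalization(np.ones((8, 8)), np.ones((8, 8)), np.zeros((8, 8), bool))


# ---------------------------------------------------------------------------
# descriptors
# ---------------------------------------------------------------------------

class TestDescriptors:
    def test_density_arithmetic(self, noiseless_field):
        """Synapse density per 100 um must equal count * 100 / length."""
        img, _ = noiseless_field
        seg = segment_field(img)
        desc = compute_morphological_descriptors(seg, img)
        n_syn = desc["synapse_count"]
        length = desc["skeleton_length_um"]
        assert desc["synapse_density_per_100um"] == pytest.approx(n_syn * 100 / length)
        assert desc["dendrite_density"] == pytest.approx(
            seg.dendrite_mask.sum() / seg.dendrite_mask.size
        )

    def test_missing_densities_without_dendrites(self):
        pixels = np.zeros((4, 1, 256, 256), dtype=np.float32)
        img = FieldImage(pixels=pixels)
        seg = segment_field(img)
        desc = compute_morphological_descriptors(seg, img)
        assert np.isnan(desc["synapse_density_per_100um"])
        assert desc["nuclei_count"] == 0

    def test_intensity_flagging(self):
        assert morpho.is_intensity_descriptor("pre_mean_intensity")
        assert morpho.is_intensity_descriptor("dendrite_mean_intensity")
        assert not morpho.is_intensity_descriptor("synapse_density_per_100um")

    def test_field_image_validation(self):
        with pytest.raises(ValueError):
            FieldImage(pixels=np.zeros((4, 1, 8, 8)), channel_roles={"nuclear": 0})
        with pytest.raises(ValueError):
            FieldImage(
                pixels=np.zeros((4, 1, 8, 8)),
                channel_roles={r: 0 for r in morpho.CHANNEL_ROLES},
            )
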