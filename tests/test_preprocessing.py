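"""Preprocessing: rasterization, crop, bilateral filter, normalization,
16-fold augmentation and patient-level splitting, each against an
independent oracle where one exists."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from meibseg.preprocessing import (
    AnnotationSet,
    AugmentToggles,
    augment_16,
    bilateral_smooth,
    crop_to_roi,
    minmax_normalize,
    rasterize_annotations,
    split_by_patient,
)

RNG = np.random.default_rng(7)


# ---------------------------------------------------------------------------
# rasterization


class TestRasterize:
    def test_axis_aligned_rectangle_pixel_count(self):
        ann = AnnotationSet([(2, 2), (5, 2), (5, 4), (2, 4)], [])
        tarsus, gland = rasterize_annotations(ann, 8, 8)
        assert tarsus.sum() == 12  # boundary-inclusive 4 x 3 block
        assert gland.sum() == 0

    def test_matches_shapely_oracle_on_random_polygons(self):
        """Even-odd pixel-center fill agrees with shapely point membership."""
        from shapely.geometry import Point, Polygon

        rng = np.random.default_rng(12)
        checked = 0
        while checked < 50:
            n = rng.integers(3, 7)
            verts = rng.uniform(0.3, 11.2, size=(n, 2))
            poly = Polygon(verts)
            if not poly.is_valid:  # self-intersecting draw: fill rules differ
                continue
            checked += 1
            mask, _ = rasterize_annotations(AnnotationSet(verts, []), 12, 12)
            for r in range(12):
                for c in range(12):
                    assert mask[r, c] == poly.intersects(Point(c, r)), (verts, r, c)

    def test_disjoint_gland_union(self):
        g1 = [(1, 1), (3, 1), (3, 3), (1, 3)]
        g2 = [(6, 6), (8, 6), (8, 8), (6, 8)]
        _, both = rasterize_annotations(AnnotationSet([(0, 0), (9, 0), (9, 9)], [g1, g2]), 10, 10)
        _, only1 = rasterize_annotations(AnnotationSet([(0, 0), (9, 0), (9, 9)], [g1]), 10, 10)
        _, only2 = rasterize_annotations(AnnotationSet([(0, 0), (9, 0), (9, 9)], [g2]), 10, 10)
        assert both.sum() == only1.sum() + only2.sum()

    def test_empty_glands_give_empty_mask(self):
        _, gland = rasterize_annotations(AnnotationSet([(0, 0), (4, 0), (4, 4)], []), 6, 6)
        assert gland.sum() == 0

    def test_rejects_degenerate_polygon(self):
        with pytest.raises(ValueError):
            AnnotationSet([(0, 0), (1, 1)], [])

    def test_out_of_bounds_vertices_clipped_with_warning(self, caplog):
        ann = AnnotationSet([(-5, -5), (20, -5), (20, 20), (-5, 20)], [])
        with caplog.at_level("WARNING"):
            mask, _ = rasterize_annotations(ann, 8, 8)
        assert mask.all()
        assert any("clipping" in r.message for r in caplog.records)


# ---------------------------------------------------------------------------
# crop


class TestCrop:
    def test_crop_produces_paper_roi(self):
        out = crop_to_roi(np.zeros((600, 1000)), 0, 0)
        assert out.shape == (420, 890)

    def test_exact_window_copy(self):
        raw = RNG.uniform(size=(500, 950))
        out = crop_to_roi(raw, 30, 40)
        np.testing.assert_array_equal(out, raw[30:450, 40:930])

    def test_identity_when_already_roi_sized(self):
        raw = RNG.uniform(size=(420, 890))
        np.testing.assert_array_equal(crop_to_roi(raw, 0, 0), raw)

    def test_rejects_small_input_with_dimensions_in_message(self):
        with pytest.raises(ValueError, match="100x100"):
            crop_to_roi(np.zeros((100, 100)), 0, 0)


# ---------------------------------------------------------------------------
# bilateral filter


def brute_bilateral(img, k, sigma_color, sigma_space):
    r = k // 2
    H, W = img.shape
    padded = np.pad(img, r, mode="edge")
    out = np.zeros_like(img)
    for i in range(H):
        for j in range(W):
            num = den = 0.0
            for dy in range(-r, r + 1):
                for dx in range(-r, r + 1):
                    q = padded[i + r + dy, j + r + dx]
                    w = np.exp(-(dy**2 + dx**2) / (2 * sigma_space**2)) * np.exp(
                        -((q - img[i, j]) ** 2) / (2 * sigma_color**2)
                    )
                    num += w * q
                    den += w
            out[i, j] = num / den
    return out


class TestBilateral:
    def test_preserves_constants(self):
        np.testing.assert_allclose(bilateral_smooth(np.full((6, 6), 0.42)), 0.42)

    def test_matches_double_loop_oracle(self):
        img = np.random.default_rng(5).uniform(size=(5, 5))
        out = bilateral_smooth(img, 3, sigma_color=0.15, sigma_space=0.8)
        np.testing.assert_allclose(out, brute_bilateral(img, 3, 0.15, 0.8), atol=1e-6)

    def test_preserves_edges_better_than_gaussian(self):
        """At a step edge the bilateral output hugs its own side."""
        from scipy.ndimage import gaussian_filter

        img = np.zeros((8, 8))
        img[:, 4:] = 1.0
        bil = bilateral_smooth(img, 3, sigma_color=0.05, sigma_space=1.0)
        gau = gaussian_filter(img, sigma=1.0, mode="nearest")
        edge_cols = [3, 4]
        for c in edge_cols:
            own_side = img[0, c]
            assert abs(bil[4, c] - own_side) < abs(gau[4, c] - own_side)

    def test_rejects_even_kernel(self):
        with pytest.raises(ValueError):
            bilateral_smooth(np.zeros((4, 4)), kernel_size=4)

    def test_output_stays_in_unit_range(self):
        img = RNG.uniform(size=(9, 9))
        out = bilateral_smooth(img)
        assert out.min() >= 0 and out.max() <= 1


# ---------------------------------------------------------------------------
# normalization


class TestNormalize:
    def test_definition(self):
        np.testing.assert_allclose(
            minmax_normalize(np.array([10.0, 20.0, 30.0])), [0.0, 0.5, 1.0]
        )

    def test_identity_when_already_normalized(self):
        img = np.array([[0.0, 0.25], [0.75, 1.0]])
        np.testing.assert_array_equal(minmax_normalize(img), img)

    def test_constant_maps_to_zeros(self):
        np.testing.assert_array_equal(minmax_normalize(np.full((3, 3), 7.0)), 0.0)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            minmax_normalize(np.array([1.0, np.nan]))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_idempotent(self, seed):
        img = np.random.default_rng(seed).uniform(-5, 5, size=(4, 5))
        once = minmax_normalize(img)
        np.testing.assert_allclose(minmax_normalize(once), once, atol=1e-12)


# ---------------------------------------------------------------------------
# augmentation


class TestAugment16:
    @pytest.fixture()
    def sample(self):
        img = np.random.default_rng(3).uniform(size=(8, 12))
        masks = {
            "tarsus": np.random.default_rng(4).uniform(size=(8, 12)) > 0.4,
            "gland": np.random.default_rng(5).uniform(size=(8, 12)) > 0.7,
        }
        return img, masks

    def test_exactly_sixteen_variants(self, sample):
        img, masks = sample
        assert len(augment_16(img, masks, seed=1)) == 16
        assert len(AugmentToggles.full_set()) == 16
        assert len(set(AugmentToggles.full_set())) == 16

    def test_all_off_variant_is_identity(self, sample):
        img, masks = sample
        v_img, v_masks, toggles = augment_16(img, masks, seed=1)[0]
        assert toggles == AugmentToggles()
        np.testing.assert_array_equal(v_img, img)
        for k in masks:
            np.testing.assert_array_equal(v_masks[k], masks[k])

    def test_flip_variant_is_involution(self, sample):
        """Reversing columns of the flip-only variant recovers the input."""
        img, masks = sample
        variants = augment_16(img, masks, seed=1)
        flip_only = [v for v in variants if v[2] == AugmentToggles(horizontal_flip=True)]
        assert len(flip_only) == 1
        v_img, v_masks, _ = flip_only[0]
        np.testing.assert_array_equal(v_img[:, ::-1], img)
        for k in masks:
            np.testing.assert_array_equal(v_masks[k][:, ::-1], masks[k])

    def test_masks_track_image_flips(self, sample):
        img, masks = sample
        for v_img, v_masks, toggles in augment_16(img, masks, seed=9):
            expect = masks["tarsus"][:, ::-1] if toggles.horizontal_flip else masks["tarsus"]
            np.testing.assert_array_equal(v_masks["tarsus"], expect)

    def test_deterministic_given_seed(self, sample):
        img, masks = sample
        a = augment_16(img, masks, seed=11)
        b = augment_16(img, masks, seed=11)
        for (ia, _, _), (ib, _, _) in zip(a, b):
            np.testing.assert_array_equal(ia, ib)

    def test_rejects_shape_mismatch(self, sample):
        img, _ = sample
        with pytest.raises(ValueError):
            augment_16(img, {"tarsus": np.zeros((4, 4))}, seed=0)


# ---------------------------------------------------------------------------
# splitting


class TestSplit:
    def test_ten_equal_patients_split_7_2_1(self):
        sa = split_by_patient([f"p{i}" for i in range(10)], seed=3)
        counts = Counter(sa.assignment.values())
        assert (counts["train"], counts["val"], counts["test"]) == (7, 2, 1)

    def test_partition_property(self):
        ids = [f"p{i}" for i in range(37) for _ in range(1 + i % 5)]
        sa = split_by_patient(ids, seed=5)
        tr, va, te = (sa.patients(n) for n in ("train", "val", "test"))
        assert tr | va | te == set(ids)
        assert not (tr & va or tr & te or va & te)

    def test_unequal_patients_hit_target_fraction(self):
        """Exhaustive recount: realized train fraction near 0.70."""
        rng = np.random.default_rng(8)
        sizes = {f"p{i}": int(rng.integers(1, 7)) for i in range(37)}
        ids = [pid for pid, n in sizes.items() for _ in range(n)]
        sa = split_by_patient(ids, seed=2)
        total = len(ids)
        train_images = sum(sizes[p] for p in sa.patients("train"))
        max_patient = max(sizes.values())
        assert abs(train_images / total - 0.70) <= max_patient / total

    def test_reproducible(self):
        ids = [f"p{i}" for i in range(12)]
        assert split_by_patient(ids, seed=4).assignment == split_by_patient(ids, seed=4).assignment

    def test_rejects_bad_fractions(self):
        with pytest.raises(ValueError):
            split_by_patient(["a", "b", "c"], fractions=(0.5, 0.3, 0.1))

    def test_rejects_too_few_patients(self):
        with pytest.raises(ValueError):
            split_by_patient(["a", "b"], seed=0)

    def test_accepts_objects_with_patient_id(self, easy_cohort):
        sa = split_by_patient(easy_cohort, seed=1)
        assert set(sa.assignment) == {s.patient_id for s in easy_cohort}
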