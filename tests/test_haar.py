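"""Haar features: integral images, template evaluation, dictionaries.

The load-bearing oracle: every feature value computed through integral-image
lookups must equal the explicit pixelwise dot product of the image with the
rendered template mask.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eustrack.haar import (
    FeatureIndex,
    HaarBasisSet,
    dictionary_from_images,
    enumerate_features,
    eval_haar_feature,
    extract_feature_vector,
    integral_image,
    build_dictionary,
)
from eustrack.volumes import GrayImage


def render_mask(basis: HaarBasisSet, idx: FeatureIndex, shape) -> np.ndarray:
    """Independent oracle: paint the weighted template onto a pixel grid."""
    sup = basis.support(idx.scale)
    mask = np.zeros(shape)
    tr, tc = idx.translation
    for x0, y0, w, h, weight in basis.templates[idx.template_id].variants[
        idx.variant_id
    ]:
        r0 = tr + int(round(y0 * sup))
        r1 = tr + int(round((y0 + h) * sup))
        c0 = tc + int(round(x0 * sup))
        c1 = tc + int(round((x0 + w) * sup))
        mask[r0:r1, c0:c1] += weight
    return mask


def _img(shape=(32, 32), seed=0):
    rng = np.random.default_rng(seed)
    return GrayImage(rng.random(shape) * 100, (1.0, 1.0))


class TestIntegralImage:
    def test_ones_and_zeros(self):
        ones = integral_image(GrayImage(np.ones((3, 3)), (1, 1)))
        assert ones[-1, -1] == 9.0
        zeros = integral_image(GrayImage(np.zeros((4, 5)), (1, 1)))
        assert np.all(zeros == 0.0)

    def test_rectangle_sums_match_bruteforce(self):
        img = _img((32, 32), seed=1)
        ii = integral_image(img)
        pad = np.zeros((33, 33))
        pad[1:, 1:] = ii
        rng = np.random.default_rng(2)
        for _ in range(100):
            r0, c0 = rng.integers(0, 31, 2)
            r1 = rng.integers(r0 + 1, 33 - 1)
            c1 = rng.integers(c0 + 1, 33 - 1)
            four = pad[r1, c1] - pad[r0, c1] - pad[r1, c0] + pad[r0, c0]
            brute = img.values[r0:r1, c0:c1].sum()
            assert abs(four - brute) <= 1e-9 * max(1.0, abs(brute))


class TestEvalFeature:
    def test_constant_image_zeroes_differential_templates(self):
        basis = HaarBasisSet(scales=(0, 1), match_size=32)
        img = GrayImage(np.full((32, 32), 7.0), (1, 1))
        ii = integral_image(img)
        for idx in enumerate_features(basis, (32, 32)):
            val = eval_haar_feature(ii, idx, basis)
            if basis.templates[idx.template_id].name == "average":
                assert val > 0
            else:
                assert abs(val) < 1e-9

    def test_vertical_step_edge_response(self):
        # left half 0 / right half 1 with the half-split vertical edge
        # template spanning the step: response = area of one half
        vals = np.zeros((8, 8))
        vals[:, 4:] = 1.0
        ii = integral_image(GrayImage(vals, (1, 1)))
        basis = HaarBasisSet(scales=(0,), base_support=8, match_size=8)
        idx = FeatureIndex(template_id=0, variant_id=1, scale=0, translation=(0, 0))
        assert eval_haar_feature(ii, idx, basis) == pytest.approx(32.0)

    def test_every_feature_matches_rendered_mask(self):
        basis = HaarBasisSet(scales=(0, 1, 2), match_size=32)
        img = _img((32, 32), seed=3)
        ii = integral_image(img)
        for idx in enumerate_features(basis, (32, 32)):
            direct = float((img.values * render_mask(basis, idx, (32, 32))).sum())
            fast = eval_haar_feature(ii, idx, basis)
            assert abs(fast - direct) <= 1e-9 * max(1.0, abs(direct))

    def test_out_of_bounds_support_rejected(self):
        basis = HaarBasisSet(scales=(0,), match_size=16)
        ii = integral_image(_img((16, 16)))
        with pytest.raises(ValueError, match="support"):
            eval_haar_feature(ii, FeatureIndex(0, 0, 0, (12, 0)), basis)


class TestEnumerate:
    def test_combinatorial_count(self):
        basis = HaarBasisSet(
            scales=(0,), base_support=8, match_size=16, template_ids=(2,)
        )
        feats = enumerate_features(basis, (16, 16))
        assert len(feats) == 4  # 2x2 translations, one template, one variant

    def test_two_scales_give_two_blocks(self):
        basis = HaarBasisSet(scales=(0, 1), match_size=32)
        vec = extract_feature_vector(_img((32, 32)), basis)
        assert len(vec.scale_blocks) == 2
        scales = sorted({b[2] for b in vec.scale_blocks})
        assert scales == [0, 1]

    def test_enumeration_deterministic(self):
        basis = HaarBasisSet(scales=(0, 1), match_size=32)
        assert enumerate_features(basis, (32, 32)) == enumerate_features(
            basis, (32, 32)
        )

    def test_image_smaller_than_support_rejected(self):
        basis = HaarBasisSet(scales=(0,), base_support=8, match_size=4)
        with pytest.raises(ValueError, match="smaller"):
            enumerate_features(basis, (4, 4))


class TestExtractVector:
    def test_linearity_in_intensity(self):
        basis = HaarBasisSet(scales=(0, 1), match_size=32)
        img = _img((32, 32), seed=4)
        doubled = GrayImage(2.0 * img.values, img.pixel_spacing)
        a = extract_feature_vector(img, basis)
        b = extract_feature_vector(doubled, basis)
        assert np.allclose(2.0 * a.values, b.values, rtol=1e-12, atol=1e-9)

    def test_full_vector_matches_bruteforce(self):
        basis = HaarBasisSet(match_size=64)
        img = _img((64, 64), seed=5)
        vec = extract_feature_vector(img, basis)
        for k in np.random.default_rng(6).choice(len(vec), 50, replace=False):
            idx = vec.index_map[k]
            direct = float((img.values * render_mask(basis, idx, (64, 64))).sum())
            assert abs(vec.values[k] - direct) <= 1e-9 * max(1.0, abs(direct))

    def test_vector_length_pure_function_of_basis_and_size(self):
        basis = HaarBasisSet(scales=(0, 1, 2), match_size=64)
        v1 = extract_feature_vector(_img((64, 64), seed=7), basis)
        v2 = extract_feature_vector(_img((64, 64), seed=8), basis)
        assert len(v1) == len(v2)
        assert v1.index_map == v2.index_map

    def test_resize_applied_for_mismatched_images(self):
        basis = HaarBasisSet(scales=(0,), match_size=32)
        vec = extract_feature_vector(_img((50, 50), seed=9), basis)
        assert len(vec) == len(enumerate_features(basis, (32, 32)))

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.floats(0.1, 10.0), st.floats(-50.0, 50.0))
    def test_affine_intensity_maps_features_affinely(self, seed, gain, bias):
        # V(a*I + b) = a*V(I) + b*V(ones): linearity of the dot product
        basis = HaarBasisSet(scales=(0, 1), match_size=16, base_support=8)
        rng = np.random.default_rng(seed)
        vals = rng.random((16, 16))
        v0 = extract_feature_vector(GrayImage(vals, (1, 1)), basis).values
        vb = extract_feature_vector(
            GrayImage(np.ones((16, 16)), (1, 1)), basis
        ).values
        va = extract_feature_vector(
            GrayImage(gain * vals + bias, (1, 1)), basis
        ).values
        assert np.allclose(va, gain * v0 + bias * vb, rtol=1e-9, atol=1e-6)


class TestDictionary:
    def test_entries_follow_grid_order(self, small_scene, small_dictionary):
        _, grid, *_ = small_scene
        assert len(small_dictionary) == len(grid)
        for entry, pose in zip(small_dictionary.entries, grid):
            assert entry.pose.label == pose.label
            assert entry.valid

    def test_rebuild_is_bitwise_identical(self, small_scene, small_dictionary):
        import eustrack as et

        spec, grid, probe, psf, field, basis = small_scene
        again = et.build_dictionary(field, grid, probe, psf, basis, image_size=64)
        for a, b in zip(small_dictionary.entries, again.entries):
            assert np.array_equal(a.vector.values, b.vector.values)

    def test_empty_grid_rejected(self, small_scene):
        from eustrack.poses import PoseGrid

        spec, grid, probe, psf, field, basis = small_scene
        with pytest.raises(ValueError, match="non-empty"):
            build_dictionary(field, PoseGrid([]), probe, psf, basis)

    def test_volume_route_builds_valid_entries(self, small_scene):
        from eustrack.phantom import generate_toy_volume

        _, _, probe, psf, _, basis = small_scene
        vol, _ = generate_toy_volume("abdomen_like", seed=2, spacing=2.0)
        from eustrack.poses import build_phantom_pose_grid

        grid = build_phantom_pose_grid(
            np.array([[0.0, 0.0, 30.0]]), n_offsets=1, rotations=(0.0,),
            extent=(80.0, 80.0), image_size=64,
        )
        d = build_dictionary(
            vol, grid, probe, psf, basis, image_size=64, bitmap_scatterers=20_000
        )
        assert len(d.valid_indices()) == 1
        assert d.entries[0].image.values.max() > 0

    def test_plane_missing_data_flagged_invalid(self, small_scene):
        from eustrack.poses import build_phantom_pose_grid

        spec, _, probe, psf, field, basis = small_scene
        grid = build_phantom_pose_grid(
            np.array([[0.0, 0.0, 500.0]]), n_offsets=1, rotations=(0.0,),
            extent=(50.0, 50.0), image_size=64,
        )
        d = build_dictionary(field, grid, probe, psf, basis, image_size=64)
        assert d.valid_indices() == []

    def test_save_writes_manifest_and_vectors(self, small_dictionary, tmp_path):
        out = tmp_path / "dict"
        small_dictionary.save(str(out))
        import json

        with open(out / "manifest.json") as fh:
            manifest = json.load(fh)
        assert manifest["basis_fingerprint"] == small_dictionary.basis_fingerprint
        vecs = np.load(out / "vectors.npy")
        assert vecs.shape[0] == len(small_dictionary.valid_indices())

    def test_dictionary_from_images_matches_build(self, small_scene,
                                                  small_dictionary):
        spec, grid, probe, psf, field, basis = small_scene
        images = [e.image for e in small_dictionary.entries]
        rebuilt = dictionary_from_images(images, grid, basis)
        for a, b in zip(small_dictionary.entries, rebuilt.entries):
            assert np.array_equal(a.vector.values, b.vector.values)
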