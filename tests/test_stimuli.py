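"""Stimulus world: rendering geometry, banks, anti-correlation."""

import numpy as np
import pytest
from scipy import stats

from stereoevo import (
    BACKGROUND_LUMINANCE,
    FIGURE_LUMINANCE,
    SceneSpec,
    SensorGeometry,
    anticorrelate,
    control_offset_bounds,
    load_bank,
    make_absolute_bank,
    make_control_bank,
    make_relative_bank,
    relative_class,
    render_stereo,
    save_bank,
)

from _oracles import oracle_eye_profile


def random_scene(rng, with_reference=False):
    """A random valid scene with half-pixel-quantized edge positions."""
    q = lambda x: round(x / 0.005) * 0.005
    kwargs = dict(
        target_disparity=q(rng.uniform(-0.18, 0.18)),
        target_offset=q(rng.uniform(-0.45, -0.15)),
    )
    if with_reference:
        kwargs.update(
            reference_offset=q(rng.uniform(-0.75, -0.55)),
            reference_disparity=q(rng.uniform(-0.18, 0.18)),
        )
    return SceneSpec(**kwargs)


class TestRenderStereo:
    def test_zero_disparity_gives_identical_images(self):
        from dataclasses import replace

        rng = np.random.default_rng(7)
        for _ in range(20):
            scene = random_scene(rng, with_reference=rng.random() < 0.5)
            scene = replace(
                scene,
                target_disparity=0.0,
                reference_disparity=0.0 if scene.has_reference else None,
            )
            pair = render_stereo(scene)
            np.testing.assert_array_equal(pair.left_profile, pair.right_profile)
            np.testing.assert_array_equal(pair.left_image, pair.right_image)

    def test_fixation_strip_occupies_30x40_pixels_at_figure_luminance(self):
        pair = render_stereo(SceneSpec())
        img = pair.left_image
        fix = img[:, 100:130]
        assert fix.shape == (40, 30)
        assert np.all(fix == FIGURE_LUMINANCE)
        assert img[0, 99] == BACKGROUND_LUMINANCE
        assert img[0, 130] == BACKGROUND_LUMINANCE

    def test_far_disparity_displaces_edges_two_pixels_in_opposite_directions(self):
        # +0.04 deg disparity = 2 px eccentric (contra) / 2 px foveal (ipsi)
        pair = render_stereo(SceneSpec(target_disparity=0.04))
        nominal = render_stereo(SceneSpec())
        bg = BACKGROUND_LUMINANCE
        first_col = lambda profile: int(np.argmax(profile > bg))
        assert first_col(nominal.left_profile) == 70
        assert first_col(pair.left_profile) == 68  # eccentric
        assert first_col(pair.right_profile) == 72  # foveal

    def test_matches_scalar_oracle_renderer(self):
        rng = np.random.default_rng(3)
        for _ in range(8):
            scene = random_scene(rng, with_reference=rng.random() < 0.5)
            pair = render_stereo(scene)
            for eye, profile in (
                ("contralateral", pair.left_profile),
                ("ipsilateral", pair.right_profile),
            ):
                oracle = oracle_eye_profile(scene, pair.geometry, eye)
                np.testing.assert_allclose(profile, oracle, atol=1e-9)

    def test_figure_area_conserved_between_eyes(self):
        # holds whenever strips stay disjoint (displacement never changes
        # strip area inside the array)
        from dataclasses import replace

        rng = np.random.default_rng(11)
        for _ in range(25):
            scene = random_scene(rng)
            scene = replace(scene, target_offset=min(scene.target_offset, -0.25))
            pair = render_stereo(scene)
            assert pair.left_profile.sum() == pytest.approx(pair.right_profile.sum())

    def test_subpixel_edges_are_area_weighted(self):
        # 0.01 deg disparity shifts each eye's edge by half a pixel
        pair = render_stereo(SceneSpec(target_disparity=0.01))
        mid = (FIGURE_LUMINANCE + BACKGROUND_LUMINANCE) / 2.0
        assert pair.left_profile[69] == pytest.approx(mid)
        assert pair.right_profile[70] == pytest.approx(mid)

    def test_rejects_out_of_span_edges(self):
        geometry = SensorGeometry()
        with pytest.raises(ValueError):
            render_stereo(SceneSpec(target_offset=-0.95, target_disparity=0.18), geometry)

    def test_rejects_invalid_scenes(self):
        with pytest.raises(ValueError):
            SceneSpec(target_disparity=0.25)
        with pytest.raises(ValueError):
            SceneSpec(figure_luminance=0.5)  # below background
        with pytest.raises(ValueError):
            SceneSpec(reference_offset=-0.6)  # disparity missing


class TestAnticorrelate:
    def test_swaps_figure_and_background(self):
        pair = render_stereo(SceneSpec())
        flipped = anticorrelate(pair, "contralateral")
        src, out = pair.left_profile, flipped.left_profile
        assert np.all(out[src == FIGURE_LUMINANCE] == BACKGROUND_LUMINANCE)
        assert np.all(out[src == BACKGROUND_LUMINANCE] == FIGURE_LUMINANCE)
        np.testing.assert_array_equal(flipped.right_profile, pair.right_profile)

    def test_double_application_is_identity(self):
        pair = render_stereo(SceneSpec(target_disparity=0.035))
        back = anticorrelate(anticorrelate(pair, "ipsilateral"), "ipsilateral")
        np.testing.assert_allclose(back.right_profile, pair.right_profile, atol=1e-12)

    def test_preserves_labels_and_shape(self):
        pair = render_stereo(
            SceneSpec(target_disparity=0.06, reference_offset=-0.6, reference_disparity=-0.02)
        )
        flipped = anticorrelate(pair, "contralateral")
        assert flipped.target_disparity == pair.target_disparity
        assert flipped.relative_disparity == pair.relative_disparity
        assert flipped.left_profile.shape == pair.left_profile.shape

    def test_rejects_out_of_range_luminances(self):
        pair = render_stereo(SceneSpec())
        bad = type(pair)(
            left_profile=pair.left_profile * 2.0,
            right_profile=pair.right_profile,
            geometry=pair.geometry,
            target_disparity=0.0,
        )
        with pytest.raises(ValueError):
            anticorrelate(bad, "contralateral")


class TestAbsoluteBank:
    def test_far_bank_labels_positive_and_sized(self):
        bank = make_absolute_bank(200, "far", seed=1)
        assert len(bank) == 200
        assert np.all(bank.labels > 0)
        assert np.all(bank.labels <= 0.18)

    def test_near_bank_labels_negative(self):
        bank = make_absolute_bank(50, "near", seed=2)
        assert np.all(bank.labels < 0)
        assert np.all(np.abs(bank.labels) <= 0.18)

    def test_same_seed_is_bit_identical(self):
        a = make_absolute_bank(30, "far", seed=5)
        b = make_absolute_bank(30, "far", seed=5)
        np.testing.assert_array_equal(a.labels, b.labels)
        for pa, pb in zip(a.pairs, b.pairs):
            np.testing.assert_array_equal(pa.left_profile, pb.left_profile)

    def test_invalid_polarity_rejected(self):
        with pytest.raises(ValueError):
            make_absolute_bank(5, "sideways", seed=0)

    def test_roundtrips_through_disk(self, tmp_path):
        bank = make_absolute_bank(12, "near", seed=9)
        save_bank(bank, tmp_path / "bank")
        loaded = load_bank(tmp_path / "bank")
        assert loaded.kind == bank.kind
        np.testing.assert_array_equal(loaded.labels, bank.labels)
        for pa, pb in zip(bank.pairs, loaded.pairs):
            np.testing.assert_array_equal(pa.left_profile, pb.left_profile)
            np.testing.assert_array_equal(pa.right_profile, pb.right_profile)


class TestRelativeBank:
    def test_relative_label_is_target_minus_reference(self):
        bank = make_relative_bank(40, polarity="rel_far", seed=3)
        for scene, label in zip(bank.scenes, bank.labels):
            assert label == pytest.approx(scene.target_disparity - scene.reference_disparity)
            assert label > 0

    def test_straddle_subtraction_example(self):
        assert relative_class(0.05, -0.05) == "straddle"
        assert 0.05 - (-0.05) == pytest.approx(0.10)

    def test_all_three_depth_classes_occur(self):
        bank = make_relative_bank(300, polarity="rel_far", seed=4)
        classes = {relative_class(s.target_disparity, s.reference_disparity) for s in bank.scenes}
        assert classes == {"both_far", "straddle", "both_near"}

    def test_class_frequencies_match_rejection_sampler(self):
        # independent uniforms conditioned on t > r: both-far 1/4,
        # straddle 1/2, both-near 1/4
        bank = make_relative_bank(6000, polarity="rel_far", seed=6)
        labels = [relative_class(s.target_disparity, s.reference_disparity) for s in bank.scenes]
        freq = {c: labels.count(c) / len(labels) for c in set(labels)}
        assert freq["both_far"] == pytest.approx(0.25, abs=0.02)
        assert freq["straddle"] == pytest.approx(0.50, abs=0.02)
        assert freq["both_near"] == pytest.approx(0.25, abs=0.02)

    def test_rel_near_signs(self):
        bank = make_relative_bank(40, polarity="rel_near", seed=8)
        assert np.all(bank.labels < 0)


class TestControlBank:
    def test_offsets_within_legal_bounds(self):
        bank = make_control_bank(200, seed=10)
        lo, hi = control_offset_bounds()
        offsets = [s.target_offset for s in bank.scenes]
        assert min(offsets) >= lo and max(offsets) <= hi

    def test_same_seed_identical(self):
        a = make_control_bank(50, seed=12)
        b = make_control_bank(50, seed=12)
        np.testing.assert_array_equal(a.labels, b.labels)
        assert [s.target_offset for s in a.scenes] == [s.target_offset for s in b.scenes]

    def test_offset_distribution_uniform(self):
        bank = make_control_bank(10_000, seed=13)
        lo, hi = control_offset_bounds()
        offsets = np.array([s.target_offset for s in bank.scenes])
        stat = stats.kstest(offsets, stats.uniform(loc=lo, scale=hi - lo).cdf)
        assert stat.pvalue > 0.01
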