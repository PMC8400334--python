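"""Two-stage detection: segmentation rules, ignored zone, envelopes,
sheet verdicts and the streaming contract."""

import numpy as np
import pytest

from kelpscan.detector import (
    BELT,
    FOREIGN,
    SEAWEED,
    DetectorParams,
    detect_sheet,
    detect_stream,
    ignored_zone,
    render_classmap,
    stage1_classify,
    stage2_inspect,
    subtraction_features,
)
from kelpscan.pipeline import calibrate_scene, reference_pixels
from kelpscan.reference_model import build_profile
from kelpscan.synthcam import ForeignObject, SceneSpec, render_scene


def _pixel(n_bands, **bands):
    """Spectrum with named 1-based band values (others zero)."""
    p = np.zeros(n_bands)
    for b, v in bands.items():
        p[int(b[1:]) - 1] = v
    return p


class TestSubtractionFeatures:
    def test_four_band_arithmetic(self, config):
        p = _pixel(112, b26=20.0, b63=85.0, b68=90.0, b93=70.0)
        sv, sn = subtraction_features(p, config)
        assert sv == 65.0 and sn == -20.0

    def test_flat_spectrum_gives_zero(self, config):
        sv, sn = subtraction_features(np.full(112, 42.0), config)
        assert sv == 0.0 and sn == 0.0

    def test_out_of_range_band_is_config_error(self, config):
        with pytest.raises(ValueError, match="band"):
            subtraction_features(np.zeros(50), config)

    def test_depends_only_on_the_four_bands(self, config, rng):
        """Permuting all non-decision bands never changes the stage-1 label."""
        pix = rng.uniform(0, 100, size=(20, 112))
        sv, sn = subtraction_features(pix, config)
        labels = stage1_classify(sv, sn, config)
        keep = {25, 62, 67, 92}
        others = [i for i in range(112) if i not in keep]
        shuffled = pix.copy()
        shuffled[:, others] = pix[:, rng.permutation(others)]
        sv2, sn2 = subtraction_features(shuffled, config)
        np.testing.assert_array_equal(stage1_classify(sv2, sn2, config), labels)


class TestStage1Classify:
    @pytest.mark.parametrize(
        "sv,sn,expected",
        [
            (65.0, -20.0, SEAWEED),  # both ranges agree on seaweed
            (30.0, 15.0, BELT),  # both agree on belt
            (50.0, -20.0, FOREIGN),  # SV in neither interval
            (65.0, 0.0, FOREIGN),  # SN in neither interval
            (90.0, 40.0, FOREIGN),  # both outside
            (65.0, 15.0, SEAWEED),  # disagreement: visible range decides
            (30.0, -20.0, BELT),  # disagreement the other way
        ],
    )
    def test_interval_rules(self, config, sv, sn, expected):
        assert stage1_classify(np.array(sv), np.array(sn), config) == expected

    def test_interval_bounds_are_inclusive(self, config):
        assert stage1_classify(np.array(60.0), np.array(-5.0), config) == SEAWEED
        assert stage1_classify(np.array(45.0), np.array(25.0), config) == BELT


class TestIgnoredZone:
    def test_belt_outside_sheet_bbox_ignored(self):
        labels = np.full((10, 1000), BELT, dtype=np.int8)
        labels[2:8, 100:901] = SEAWEED
        mask = ignored_zone(labels, "outside_sheet_bbox")
        assert mask[5, 50] and mask[5, 950]  # belt columns <100 and >900
        assert not mask[5, 500]  # inside the bbox nothing is ignored
        assert mask[0, 500]  # belt rows before the sheet
        assert not mask[2:8, 100:901].any()

    def test_belt_inside_bbox_stays_inspected(self):
        labels = np.full((6, 6), BELT, dtype=np.int8)
        labels[1, 1] = labels[4, 4] = SEAWEED
        mask = ignored_zone(labels, "outside_sheet_bbox")
        assert not mask[2, 2]  # belt pixel inside the seaweed bbox

    def test_mode_none_is_empty(self):
        labels = np.full((3, 3), BELT, dtype=np.int8)
        assert not ignored_zone(labels, "none").any()

    def test_all_belt_everything_ignored_with_warning(self):
        labels = np.full((3, 3), BELT, dtype=np.int8)
        with pytest.warns(UserWarning, match="no seaweed"):
            assert ignored_zone(labels, "outside_sheet_bbox").all()


@pytest.fixture(scope="module")
def profile():
    rng = np.random.default_rng(9)
    return build_profile(rng.normal(50, 4, size=(300, 8)), "seaweed")


class TestStage2Inspect:

    def test_profile_mean_is_clean_at_any_margin(self, profile):
        for margin in (0.0, 1.0, 3.0):
            assert not stage2_inspect(profile.mean, profile, margin)

    def test_boundary_excursion_flagged(self, profile):
        pix = profile.mean.copy()
        pix[3] = profile.mean[3] + (profile.env_high[3] + 3.0 + 0.1) * profile.std[3]
        assert stage2_inspect(pix, profile, 3.0)
        pix[3] = profile.mean[3] + (profile.env_high[3] + 3.0 - 0.1) * profile.std[3]
        assert not stage2_inspect(pix, profile, 3.0)

    def test_reference_pixels_clean_at_margin_zero(self, rng):
        pixels = rng.normal(20, 2, size=(200, 6))
        prof = build_profile(pixels, "belt")
        assert not stage2_inspect(pixels, prof, 0.0).any()

    def test_foreign_set_shrinks_as_margin_grows(self, profile, rng):
        pixels = rng.normal(50, 12, size=(500, 8))  # wider than the reference
        flagged = [set(np.nonzero(stage2_inspect(pixels, profile, m))[0]) for m in (0, 1, 3, 5)]
        assert flagged[0] >= flagged[1] >= flagged[2] >= flagged[3]
        assert len(flagged[0]) > len(flagged[3])  # the margins actually bite


@pytest.fixture(scope="module")
def params(config):
    return DetectorParams(subtraction=config)


class TestDetectSheet:

    def _scene(self, materials, seed, objects=()):
        spec = SceneSpec(
            samples_per_line=256, pixel_pitch_mm=1.0, sheet_shape="square",
            seed=seed, foreign_objects=list(objects),
        )
        return render_scene(spec, materials)

    def test_clean_sheet_accepted_with_zero_foreign(self, materials, params, profiles):
        scene = self._scene(materials, seed=21)
        cmap, verdict = detect_sheet(calibrate_scene(scene), params, profiles)
        assert verdict.decision == "accept"
        assert verdict.foreign_pixel_count == 0

    def test_shrimp_patch_caught_at_stage_1(self, materials, params, profiles):
        scene = self._scene(materials, 22, [ForeignObject("shrimp_shell", 40, 60, 3, 3)])
        cmap, verdict = detect_sheet(calibrate_scene(scene), params, profiles)
        assert verdict.decision == "reject"
        assert cmap.stage1_foreign.sum() >= 9
        truth = scene.mask >= 2
        assert (cmap.stage1_foreign & truth).sum() == 9

    def test_plastic_patch_caught_only_at_stage_2(self, materials, params, profiles):
        scene = self._scene(materials, 23, [ForeignObject("plastic", 80, 80, 3, 3)])
        cmap, verdict = detect_sheet(calibrate_scene(scene), params, profiles)
        truth = scene.mask >= 2
        assert verdict.decision == "reject"
        assert not (cmap.stage1_foreign & truth).any()  # invisible to subtraction
        assert (cmap.stage2_foreign & truth).sum() == 9  # envelope catches all of it

    def test_profile_band_mismatch_rejected(self, materials, params):
        scene = self._scene(materials, 24)
        bad = {
            "seaweed": build_profile(np.random.default_rng(0).normal(50, 4, (10, 8)), "seaweed"),
            "belt": build_profile(np.random.default_rng(1).normal(50, 4, (10, 8)), "belt"),
        }
        with pytest.raises(ValueError, match="bands"):
            detect_sheet(calibrate_scene(scene), params, bad)

    def test_verdict_threshold(self, materials, config, profiles):
        scene = self._scene(materials, 25, [ForeignObject("thread", 30, 30, 2, 2)])
        strict = DetectorParams(subtraction=config, min_foreign_pixels=1)
        lax = DetectorParams(subtraction=config, min_foreign_pixels=50)
        _, v1 = detect_sheet(calibrate_scene(scene), strict, profiles)
        _, v2 = detect_sheet(calibrate_scene(scene), lax, profiles)
        assert v1.decision == "reject" and v2.decision == "accept"
        assert v1.foreign_pixel_count == v2.foreign_pixel_count


class TestStreaming:
    def test_streaming_equals_batch_with_ignored_zone_off(self, materials, config, profiles):
        params = DetectorParams(subtraction=config, ignored_zone_mode="none")
        scene = render_scene(
            SceneSpec(samples_per_line=128, pixel_pitch_mm=2.0, sheet_shape="square",
                      seed=31, foreign_objects=[ForeignObject("plastic", 10, 10, 2, 2)]),
            materials,
        )
        cal = calibrate_scene(scene)
        batch_map, batch_v = detect_sheet(cal, params, profiles)
        stream_map, stream_v = detect_stream(iter(cal.data), params, profiles)
        np.testing.assert_array_equal(stream_map.labels, batch_map.labels)
        np.testing.assert_array_equal(stream_map.stage2_foreign, batch_map.stage2_foreign)
        assert stream_v == batch_v


class TestRenderClassmap:
    def _map(self, labels, ignored=None):
        from kelpscan.detector import ClassMap

        labels = np.asarray(labels, dtype=np.int8)
        z = np.zeros(labels.shape, dtype=bool)
        return ClassMap(labels, ignored if ignored is not None else z, z.copy(), z.copy())

    def test_palette(self):
        rgb = render_classmap(self._map([[SEAWEED, BELT, FOREIGN]]))
        np.testing.assert_array_equal(rgb[0, 0], [0, 0, 0])
        np.testing.assert_array_equal(rgb[0, 1], [255, 255, 255])
        np.testing.assert_array_equal(rgb[0, 2], [255, 0, 0])

    def test_single_foreign_pixel_is_single_red_pixel(self):
        labels = np.full((4, 4), SEAWEED, dtype=np.int8)
        labels[2, 2] = FOREIGN
        rgb = render_classmap(self._map(labels))
        red = (rgb == [255, 0, 0]).all(axis=2)
        assert red.sum() == 1 and red[2, 2]

    def test_histogram_bijection_and_ignored_rendered_white(self, rng):
        labels = rng.integers(0, 3, size=(20, 20)).astype(np.int8)
        rgb = render_classmap(self._map(labels))
        for code, color in ((SEAWEED, (0, 0, 0)), (BELT, (255, 255, 255)), (FOREIGN, (255, 0, 0))):
            assert ((rgb == color).all(axis=2).sum()) == (labels == code).sum()
        ignored = np.zeros(labels.shape, dtype=bool)
        ignored[labels == SEAWEED] = True  # pathological but pins the rule
        rgb2 = render_classmap(self._map(labels, ignored))
        assert (rgb2[ignored & (labels != FOREIGN)] == 255).all()
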