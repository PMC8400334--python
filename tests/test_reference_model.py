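"""Reference statistics, envelopes, band-pair search and intervals."""

import numpy as np
import pytest

from kelpscan.detector import subtraction_features
from kelpscan.reference_model import (
    ReferenceProfile,
    SubtractionConfig,
    build_profile,
    default_subtraction_config,
    derive_intervals,
    load_profiles,
    save_profiles,
    select_band_pair,
    standardize,
)


class TestBuildProfile:
    def test_two_pixel_hand_computation(self):
        # pixels (0,10) and (10,0): mu=(5,5), population sigma=(5,5),
        # standardized pixels are +-1 -> envelope exactly [-1, 1].
        prof = build_profile(np.array([[0.0, 10.0], [10.0, 0.0]]), "seaweed")
        np.testing.assert_allclose(prof.mean, [5.0, 5.0])
        np.testing.assert_allclose(prof.std, [5.0, 5.0])
        np.testing.assert_allclose(prof.env_low, [-1.0, -1.0])
        np.testing.assert_allclose(prof.env_high, [1.0, 1.0])
        assert prof.n_pixels == 2

    def test_identical_pixels_name_zero_sigma_band(self):
        with pytest.raises(ValueError, match=r"band\(s\) \[1, 2\]"):
            build_profile(np.array([[3.0, 4.0], [3.0, 4.0]]), "belt")

    def test_envelope_brackets_zero_and_contains_all_reference_pixels(self, rng):
        pixels = rng.normal(50, 5, size=(500, 12))
        prof = build_profile(pixels, "seaweed")
        assert (prof.env_low <= 0).all() and (prof.env_high >= 0).all()
        z = standardize(pixels, prof)
        assert (z >= prof.env_low - 1e-12).all() and (z <= prof.env_high + 1e-12).all()

    def test_envelope_grows_monotonically_with_reference_set(self, rng):
        pixels = rng.normal(0, 1, size=(200, 6))
        small = build_profile(pixels[:50], "belt")
        # standardize both envelopes against the same (small) profile to
        # compare raw spreads: the larger set's raw min/max bracket the
        # smaller set's.
        assert (pixels[:50].min(axis=0) >= pixels.min(axis=0)).all()
        assert (pixels[:50].max(axis=0) <= pixels.max(axis=0)).all()
        large = build_profile(pixels, "belt")
        raw_lo_small = small.mean + small.env_low * small.std
        raw_lo_large = large.mean + large.env_low * large.std
        assert (raw_lo_large <= raw_lo_small + 1e-9).all()


class TestStandardize:
    def test_mean_maps_to_zero_and_sigma_steps(self):
        prof = build_profile(np.array([[0.0, 10.0], [10.0, 0.0], [5.0, 5.0]]), "seaweed")
        np.testing.assert_allclose(standardize(prof.mean, prof), 0.0, atol=1e-12)
        np.testing.assert_allclose(standardize(prof.mean + prof.std, prof), 1.0)
        np.testing.assert_allclose(standardize(prof.mean - 2 * prof.std, prof), -2.0)

    def test_band_count_mismatch(self):
        prof = build_profile(np.array([[0.0, 10.0], [10.0, 0.0]]), "seaweed")
        with pytest.raises(ValueError):
            standardize(np.zeros(3), prof)


def _profile_from_means(means, name="x"):
    means = np.asarray(means, dtype=float)
    return ReferenceProfile(
        class_name=name,
        mean=means,
        std=np.ones_like(means),
        env_low=np.zeros_like(means),
        env_high=np.zeros_like(means),
        n_pixels=2,
    )


def _brute_force_pair(mean_a, mean_b, idx):
    best = (-1.0, None)
    for ii in range(len(idx)):
        for jj in range(ii + 1, len(idx)):
            i, j = idx[ii], idx[jj]
            sep = abs((mean_a[j] - mean_a[i]) - (mean_b[j] - mean_b[i]))
            if sep > best[0]:
                best = (sep, (i + 1, j + 1))
    return best[1] + (best[0],)


class TestSelectBandPair:
    def test_constructed_argmax_recovered(self):
        wl = 400.0 + 10.0 * np.arange(10)
        a = np.zeros(10)
        b = np.zeros(10)
        a[2], a[7] = -5.0, 35.0  # separation 40 at pair (3, 8), others <= 35
        assert select_band_pair(
            _profile_from_means(a), _profile_from_means(b), (400, 500), wl
        ) == (3, 8, 40.0)

    def test_identical_profiles_tie_break_lexicographic(self):
        wl = 400.0 + 10.0 * np.arange(5)
        a = _profile_from_means(np.zeros(5))
        assert select_band_pair(a, a, (400, 500), wl) == (1, 2, 0.0)

    def test_matches_brute_force_on_100_random_profile_pairs(self):
        rng = np.random.default_rng(77)
        wl = 400.0 + 5.0 * np.arange(20)
        for _ in range(100):
            a = rng.integers(0, 50, size=20).astype(float)  # integer means force ties
            b = rng.integers(0, 50, size=20).astype(float)
            idx = list(range(20))
            expected = _brute_force_pair(a, b, idx)
            got = select_band_pair(_profile_from_means(a), _profile_from_means(b), (400, 500), wl)
            assert got == expected

    def test_range_restricts_the_search(self):
        wl = np.array([400.0, 500.0, 800.0, 900.0])
        a = _profile_from_means([0.0, 1.0, 0.0, 100.0])
        b = _profile_from_means([0.0, 0.0, 0.0, 0.0])
        band_lo, band_hi, sep = select_band_pair(a, b, (750, 1000), wl)
        assert (band_lo, band_hi) == (3, 4) and sep == 100.0
        with pytest.raises(ValueError):
            select_band_pair(a, b, (600, 700), wl)


class TestSubtractionConfig:
    def test_bundled_defaults_carry_published_intervals(self):
        cfg = default_subtraction_config()
        assert cfg.visible_pair == (26, 63) and cfg.nir_pair == (68, 93)
        assert cfg.visible_intervals == {"seaweed": (60.0, 80.0), "belt": (20.0, 45.0)}
        assert cfg.nir_intervals == {"seaweed": (-30.0, -5.0), "belt": (5.0, 25.0)}

    def test_default_bands_sit_in_their_nm_ranges_on_the_112_grid(self):
        from kelpscan.synthcam import default_wavelengths

        default_subtraction_config().validate_against(default_wavelengths())

    def test_overlapping_intervals_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            SubtractionConfig(
                visible_pair=(1, 2),
                nir_pair=(3, 4),
                visible_intervals={"seaweed": (10, 50), "belt": (40, 60)},
                nir_intervals={"seaweed": (-10, -5), "belt": (5, 10)},
            )


class TestDeriveIntervals:
    def test_recovers_generator_ranges(self, rng):
        cfg = default_subtraction_config()
        n_bands = 112
        # construct pixels whose subtraction values land in known ranges
        def pixels(sv_range, sn_range, n=200):
            p = np.zeros((n, n_bands))
            p[:, cfg.visible_pair[1] - 1] = rng.uniform(*sv_range, size=n)
            p[:, cfg.nir_pair[1] - 1] = rng.uniform(*sn_range, size=n)
            return p

        derived = derive_intervals(
            {"seaweed": pixels((62, 78), (8, 20)), "belt": pixels((25, 40), (-20, -8))},
            cfg,
        )
        lo, hi = derived.visible_intervals["seaweed"]
        assert 62 <= lo <= 63 and 77 <= hi <= 78
        lo, hi = derived.nir_intervals["belt"]
        assert -20 <= lo <= -19 and -9 <= hi <= -8

    def test_single_pixel_class_degenerate_with_warning(self):
        cfg = default_subtraction_config()
        a = np.zeros((1, 112))
        a[0, cfg.visible_pair[1] - 1] = 70.0
        b = np.zeros((2, 112))
        b[:, cfg.visible_pair[1] - 1] = (30.0, 31.0)
        b[:, cfg.nir_pair[1] - 1] = 10.0
        with pytest.warns(UserWarning, match="single reference pixel"):
            derived = derive_intervals({"seaweed": a, "belt": b}, cfg)
        assert derived.visible_intervals["seaweed"] == (70.0, 70.0)

    def test_inseparable_classes_error(self):
        cfg = default_subtraction_config()
        same = np.zeros((2, 112))
        same[:, cfg.visible_pair[1] - 1] = 50.0
        with pytest.raises(ValueError, match="overlap"):
            derive_intervals({"seaweed": same, "belt": same.copy()}, cfg)

    def test_synthetic_class_features_land_in_published_intervals(self, materials, config):
        from kelpscan.pipeline import reference_pixels

        for cls in ("seaweed", "belt"):
            sv, sn = subtraction_features(
                reference_pixels(materials[cls], 1000, seed=5), config
            )
            vlo, vhi = config.visible_intervals[cls]
            nlo, nhi = config.nir_intervals[cls]
            assert ((sv >= vlo) & (sv <= vhi)).all()
            assert ((sn >= nlo) & (sn <= nhi)).all()


def test_profile_table_roundtrip(tmp_path, profiles):
    path = save_profiles(profiles, tmp_path / "profiles.tsv")
    back = load_profiles(path)
    assert set(back) == set(profiles)
    for cls in profiles:
        np.testing.assert_array_equal(back[cls].mean, profiles[cls].mean)
        np.testing.assert_array_equal(back[cls].std, profiles[cls].std)
        np.testing.assert_array_equal(back[cls].env_low, profiles[cls].env_low)
        np.testing.assert_array_equal(back[cls].env_high, profiles[cls].env_high)
        assert back[cls].n_pixels == profiles[cls].n_pixels
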