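"""Segmentation, straightening and profile-fit accuracy against the
generator's analytic ground truth."""

import numpy as np
import pytest

from parmap import cortex, synthetic
from parmap.errors import SegmentationError, StraighteningError, ValidationError
from parmap.images import EmbryoImage
from parmap.profilemodel import gauss_erf_profile


def ramanujan_perimeter(a, b):
    h = ((a - b) / (a + b)) ** 2
    return np.pi * (a + b) * (1 + 3 * h / (10 + np.sqrt(4 - 3 * h)))


class TestSegmentEmbryo:
    def test_perimeter_and_area_match_analytic_ellipse(self, segmented_embryo):
        image, truth, contour = segmented_embryo
        expected = ramanujan_perimeter(25.0, 15.0)
        assert contour.perimeter_um == pytest.approx(expected, rel=0.01)
        area = contour.mask.sum() * image.pixel_scale**2
        assert area == pytest.approx(np.pi * 25.0 * 15.0, rel=0.01)

    def test_blank_image_fails(self):
        img = EmbryoImage(np.zeros((2, 100, 100)), 0.256, {"signal": 0, "af": 1})
        with pytest.raises(SegmentationError):
            cortex.segment_embryo(img, channel="signal")

    def test_anterior_anchor_follows_marker(self, segmented_embryo):
        """s=0 sits at the pole where the anterior marker (aPAR) plateau is
        high; the true anterior pole is at image x = -a."""
        image, truth, contour = segmented_embryo
        H, W = image.shape
        cx = (W - 1) / 2.0
        x_um = (contour.points[0, 1] - cx) * image.pixel_scale
        assert x_um == pytest.approx(-25.0, abs=1.0)

    def test_contour_uniform_arc_length(self, segmented_embryo):
        _, _, contour = segmented_embryo
        seg = np.hypot(*np.diff(contour.points, axis=0).T)
        assert np.ptp(seg) / seg.mean() < 0.05


class TestStraightenCortex:
    def test_constant_image_stays_constant(self, segmented_embryo):
        image, _, contour = segmented_embryo
        const = EmbryoImage(
            np.full((1,) + image.shape, 7.5), image.pixel_scale, {"signal": 0}
        )
        st = cortex.straighten_cortex(const, contour, channel="signal")
        np.testing.assert_allclose(st.raster, 7.5, rtol=1e-9)

    def test_rows_match_forward_model(self, segmented_embryo):
        """Noiseless rendered embryo: every unsmoothed row equals the
        analytic Gaussian + step profile at that perimeter position
        (RMS < 2% of the local peak)."""
        image, truth, contour = segmented_embryo
        st = cortex.straighten_cortex(image, contour, channel="apar", smooth_window_px=1)
        model = synthetic.MembraneModel(100.0, 25.0, 0.25, 20.0)
        rms_rel = []
        for i in range(0, len(st.s), 37):
            amp = float(model.amplitude(st.s[i]))
            expected = gauss_erf_profile(st.x_um, amp, 50.0, 0.0, 0.5, 0.5)
            rms = np.sqrt(np.mean((st.raster[i] - expected) ** 2))
            rms_rel.append(rms / expected.max())
        assert np.mean(rms_rel) < 0.02

    def test_window_of_one_is_identity(self, segmented_embryo):
        image, _, contour = segmented_embryo
        st1 = cortex.straighten_cortex(image, contour, channel="apar", smooth_window_px=1)
        st0 = cortex.straighten_cortex(image, contour, channel="apar", smooth_window_px=0)
        np.testing.assert_array_equal(st1.raster, st0.raster)

    def test_circular_smoothing_conserves_column_means(self, segmented_embryo):
        image, _, contour = segmented_embryo
        raw = cortex.straighten_cortex(image, contour, channel="apar", smooth_window_px=1)
        smoothed = cortex.straighten_cortex(image, contour, channel="apar", smooth_window_px=20)
        np.testing.assert_allclose(
            raw.raster.mean(axis=0), smoothed.raster.mean(axis=0), rtol=1e-10
        )

    def test_band_leaving_image_is_reported(self, segmented_embryo):
        image, _, contour = segmented_embryo
        with pytest.raises(StraighteningError) as exc:
            cortex.straighten_cortex(image, contour, channel="apar", width_px=200)
        assert len(exc.value.positions) > 0


def _synthetic_straightened(n_positions=100, amplitude=100.0, cytoplasm=50.0,
                            noise_sd=0.0, seed=0, width_px=50, smooth_window_px=1):
    x_um = (np.arange(width_px) - (width_px - 1) / 2.0) * 0.256
    rng = np.random.default_rng(seed)
    base = gauss_erf_profile(x_um, amplitude, cytoplasm, 0.0, 0.5, 0.5)
    raster = np.tile(base, (n_positions, 1))
    if noise_sd > 0:
        raster = raster + rng.normal(0, noise_sd, raster.shape)
    if smooth_window_px > 1:
        from scipy.ndimage import uniform_filter1d

        raster = uniform_filter1d(raster, smooth_window_px, axis=0, mode="wrap")
    return cortex.StraightenedCortex(
        raster=raster,
        x_um=x_um,
        s=np.arange(n_positions) / n_positions,
        pixel_scale=0.256,
        width_px=width_px,
        smooth_window_px=smooth_window_px,
    )


class TestFitMembraneProfiles:
    def test_noiseless_recovery(self):
        st = _synthetic_straightened()
        prof = cortex.fit_membrane_profiles(st)
        np.testing.assert_allclose(prof.amplitude, 100.0, rtol=0.005)
        np.testing.assert_allclose(prof.cytoplasm, 50.0, rtol=0.005)

    def test_noisy_recovery_within_five_percent_rms(self):
        st = _synthetic_straightened(noise_sd=2.0, seed=5)
        prof = cortex.fit_membrane_profiles(st)
        rms = np.sqrt(np.mean((prof.amplitude - 100.0) ** 2))
        assert rms / 100.0 < 0.05

    def test_step_only_profile_has_no_membrane(self):
        """A pure cytoplasmic step fits with zero membrane amplitude when
        noiseless, and only noise-floor amplitude at modest noise (a centre
        shift trades off against a small Gaussian for step-only profiles,
        so the floor is amplified relative to the raw pixel noise)."""
        clean = cortex.fit_membrane_profiles(_synthetic_straightened(amplitude=0.0))
        assert np.nanmax(clean.amplitude) < 0.5  # <1% of the plateau
        st = _synthetic_straightened(amplitude=0.0, noise_sd=0.02, seed=6, smooth_window_px=20)
        prof = cortex.fit_membrane_profiles(st)
        assert np.nanmax(prof.amplitude) < 2.0

    def test_linearity_in_intensity(self):
        st = _synthetic_straightened()
        st2 = cortex.StraightenedCortex(
            raster=2.0 * st.raster, x_um=st.x_um, s=st.s,
            pixel_scale=st.pixel_scale, width_px=st.width_px, smooth_window_px=1,
        )
        p1 = cortex.fit_membrane_profiles(st)
        p2 = cortex.fit_membrane_profiles(st2)
        np.testing.assert_allclose(p2.amplitude, 2.0 * p1.amplitude, rtol=1e-5)
        np.testing.assert_allclose(p2.cytoplasm, 2.0 * p1.cytoplasm, rtol=1e-5)

    def test_narrow_band_rejected(self):
        st = _synthetic_straightened(width_px=15)
        with pytest.raises(ValidationError):
            cortex.fit_membrane_profiles(st)


class TestRoundTrip:
    def test_amplitude_recovered_away_from_boundary(self, fitted_profiles):
        """render -> segment -> straighten -> fit recovers A_true(s) within
        2% (noiseless), excluding the logistic transition zones."""
        _, truth, _, profiles = fitted_profiles
        prof = profiles["apar"]
        model = synthetic.MembraneModel(100.0, 25.0, 0.25, 20.0)
        true_amp = model.amplitude(prof.s)
        u = np.minimum(prof.s, 1 - prof.s)
        away = np.abs(u - 0.25) > 0.06
        rel = np.abs(prof.amplitude[away] - true_amp[away]) / true_amp[away]
        assert np.quantile(rel, 0.95) < 0.02

    def test_rotation_invariance(self, polarized_embryo):
        """Rotating the image by 90 degrees changes cortical means by <1%."""
        _, image, _ = polarized_embryo
        rot = EmbryoImage(
            np.rot90(image.data, axes=(1, 2)).copy(), image.pixel_scale, image.channel_roles
        )
        means = {}
        for img, key in ((image, "orig"), (rot, "rot")):
            c = cortex.segment_embryo(img, channel="apar", anterior_marker="apar")
            st = cortex.straighten_cortex(img, c, channel="apar")
            p = cortex.fit_membrane_profiles(st)
            means[key] = (
                cortex.cortical_mean(p, "anterior"),
                cortex.cortical_mean(p, "posterior"),
            )
        for a, b in zip(means["orig"], means["rot"]):
            assert a == pytest.approx(b, rel=0.01)


class TestCorticalMeanAndDosage:
    def test_uniform_profile_any_region(self):
        from conftest import membrane_profile_from_amplitude

        s = np.arange(200) / 200
        prof = membrane_profile_from_amplitude(s, np.full(200, 80.0))
        assert cortex.cortical_mean(prof, "anterior") == pytest.approx(80.0)
        assert cortex.cortical_mean(prof, "posterior") == pytest.approx(80.0)

    def test_piecewise_profile_separates_poles(self):
        from conftest import membrane_profile_from_amplitude

        s = np.arange(2000) / 2000
        amp = np.where((s >= 0.35) & (s <= 0.65), 100.0, 0.0)
        prof = membrane_profile_from_amplitude(s, amp)
        assert cortex.cortical_mean(prof, "posterior", 0.30) == pytest.approx(100.0)
        assert cortex.cortical_mean(prof, "anterior", 0.30) == pytest.approx(0.0)

    def test_full_fraction_is_global_mean(self):
        from conftest import membrane_profile_from_amplitude

        rng = np.random.default_rng(8)
        amp = rng.uniform(0, 100, 500)
        prof = membrane_profile_from_amplitude(np.arange(500) / 500, amp)
        assert cortex.cortical_mean(prof, "anterior", 1.0) == pytest.approx(amp.mean())

    def test_total_dosage_examples(self, segmented_embryo):
        image, _, contour = segmented_embryo
        mean = cortex.whole_embryo_mean(image, contour.mask, "apar")
        assert cortex.total_dosage(image, contour.mask, mean, "apar") == pytest.approx(1.0)
        half = EmbryoImage(image.data * 0.5, image.pixel_scale, image.channel_roles)
        assert cortex.total_dosage(half, contour.mask, mean, "apar") == pytest.approx(0.5)
        with pytest.raises(ValidationError):
            cortex.total_dosage(image, contour.mask, 0.0, "apar")

    def test_dosage_cohort_recovery(self):
        """Noiseless rundown embryos: measured dosage within 2% of truth."""
        ctrl_spec = synthetic.polarized_embryo_spec(asi=0.9, dosage=1.0, seed=60)
        ctrl_img, ctrl_gt = synthetic.render_embryo(ctrl_spec)
        ctrl_mean = ctrl_img.channel("apar")[ctrl_gt.mask].mean()
        for d in (0.75, 0.25):
            spec = synthetic.polarized_embryo_spec(asi=0.9, dosage=d, seed=61)
            img, gt = synthetic.render_embryo(spec)
            meas = img.channel("apar")[gt.mask].mean() / ctrl_mean
            assert meas == pytest.approx(d, rel=0.02)


class TestAverageProfilesByDosage:
    def test_single_nearest_and_identical_profiles(self):
        profiles = np.tile(np.linspace(0, 1, 50), (7, 1))
        dosages = np.array([1.0, 0.9, 0.8, 0.7, 0.6, 0.5, 0.4])
        out = cortex.average_profiles_by_dosage(profiles, dosages, levels=[0.62], k=1)
        assert out[0.62].indices == [4]
        np.testing.assert_array_equal(out[0.62].sd, 0.0)
        out7 = cortex.average_profiles_by_dosage(profiles, dosages, levels=[0.7], k=7)
        np.testing.assert_allclose(out7[0.7].mean, profiles[0])
        np.testing.assert_allclose(out7[0.7].sd, 0.0, atol=1e-12)

    def test_binned_means_recover_generator_truth(self):
        rng = np.random.default_rng(9)
        s = np.arange(100) / 100
        levels = [1.0, 0.5]
        profiles, dosages = [], []
        for level in levels:
            for _ in range(10):
                profiles.append(level * 100.0 * np.ones(100) + rng.normal(0, 2, 100))
                dosages.append(level + rng.normal(0, 0.02))
        out = cortex.average_profiles_by_dosage(np.array(profiles), np.array(dosages), levels, k=7)
        for level in levels:
            se = 2.0 / np.sqrt(7)
            assert np.all(np.abs(out[level].mean - 100.0 * level) < 4 * se)

    def test_too_few_embryos_rejected(self):
        with pytest.raises(ValidationError):
            cortex.average_profiles_by_dosage(np.ones((3, 10)), np.ones(3), k=7)
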