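"""Line-profile FWHM, intensities, density, and representative sampling."""

import math
import warnings

import numpy as np
import pytest

from azpunct.core import FWHM_PER_SIGMA, NoCrossingError, PunctumRecord
from azpunct.metrics import (
    LineProfile,
    extract_profile,
    intensity_per_area,
    intensity_per_punctum,
    measure_fwhm,
    measure_puncta_fwhm,
    puncta_density,
    sample_representative_puncta,
)
from azpunct.segment import segment_puncta
from azpunct.simgen import realize_mask, render_channel

from conftest import image_of, make_single_punctum_scene


def gaussian_profile(fwhm_nm, step_nm=10.0, half_len_nm=300.0, amp=100.0,
                     bg=0.0):
    x = np.arange(-half_len_nm, half_len_nm + step_nm / 2, step_nm)
    sigma = fwhm_nm / FWHM_PER_SIGMA
    return LineProfile(positions_nm=x - x[0],
                       intensities=bg + amp * np.exp(-x**2 / (2 * sigma**2)),
                       background_estimate=bg)


def dense_fwhm_oracle(fwhm_nm, amp=100.0, bg=0.0):
    """FWHM read off a 0.1 nm sampled Gaussian by the same half-max rule."""
    x = np.arange(-400.0, 400.0001, 0.1)
    sigma = fwhm_nm / FWHM_PER_SIGMA
    y = bg + amp * np.exp(-x**2 / (2 * sigma**2))
    half = bg + (y.max() - bg) / 2
    above = np.nonzero(y >= half)[0]
    return x[above[-1]] - x[above[0]]


def segmented_single_punctum(scene):
    img = render_channel(scene, "ch")
    mask = realize_mask(scene.mask_spec, scene.width_px, scene.height_px,
                        scene.pixel_size_nm)
    ps = segment_puncta(img, 0.05 * img.pixels.max(), mask)
    assert len(ps) == 1
    return img, ps


class TestExtractProfile:
    def test_profile_symmetric_for_isotropic_punctum(self):
        scene = make_single_punctum_scene(1290.0, 1290.0)  # on a pixel centre
        img, ps = segmented_single_punctum(scene)
        prof = extract_profile(img, ps.puncta[0], label_image=ps.label_image)
        y = prof.intensities
        i = int(np.argmax(y))
        k = min(i, y.size - 1 - i)
        np.testing.assert_allclose(y[i - k:i], y[i + k:i:-1], atol=1e-6)

    def test_constant_image_background(self, full_mask):
        img = image_of(np.full((128, 128), 13.0))
        rec = PunctumRecord(1, 1280.0, 1280.0, 9, 0.0036, 13, 13, 117)
        prof = extract_profile(img, rec, length_nm=600.0)
        assert np.all(prof.intensities == 13.0)
        assert prof.background_estimate == 13.0

    def test_orientation_follows_major_axis(self):
        """Anisotropic blob (sigma_x > sigma_y): the chosen line lies within
        5 degrees of the x axis (second-moment eigenvector oracle)."""
        rows, cols = np.mgrid[0:128, 0:128]
        x = (cols + 0.5) * 20.0
        y = (rows + 0.5) * 20.0
        img = 100.0 * np.exp(-((x - 1280) ** 2 / (2 * 90.0**2)
                               + (y - 1280) ** 2 / (2 * 45.0**2)))
        from azpunct.metrics import _principal_axis
        region = img > 5.0
        ux, uy = _principal_axis(img, region)
        angle = math.degrees(math.atan2(abs(uy), abs(ux)))
        assert angle < 5.0

    def test_border_punctum_rejected(self):
        from azpunct.core import ProfileBoundsError
        rec = PunctumRecord(1, 10.0, 10.0, 9, 0.0036, 1, 1, 9,
                            border_flag=True)
        with pytest.raises(ProfileBoundsError):
            extract_profile(image_of(np.ones((64, 64))), rec)


class TestMeasureFwhm:
    @pytest.mark.parametrize("fwhm", [60.0, 100.0, 160.0])
    def test_ideal_gaussian_profile(self, fwhm):
        """10 nm sampled Gaussian profile: estimate within 1 nm of the dense
        0.1 nm oracle."""
        est = measure_fwhm(gaussian_profile(fwhm))
        assert est == pytest.approx(dense_fwhm_oracle(fwhm), abs=1.0)

    def test_triangular_profile_exact(self):
        """Baseline 10, peak 50, linear rise/fall over 100 nm each side:
        half-height 30, FWHM exactly 100 nm."""
        x = np.arange(0.0, 210.0, 10.0)
        y = np.where(np.abs(x - 100.0) <= 100.0,
                     50.0 - 40.0 * np.abs(x - 100.0) / 100.0, 10.0)
        prof = LineProfile(x, y, background_estimate=10.0)
        assert measure_fwhm(prof) == pytest.approx(100.0, abs=1e-9)

    def test_flat_profile_rejected(self):
        prof = LineProfile(np.arange(0.0, 100.0, 10.0), np.full(10, 5.0), 5.0)
        with pytest.raises(NoCrossingError):
            measure_fwhm(prof)

    def test_truncated_profile_rejected(self):
        x = np.arange(0.0, 200.0, 10.0)
        y = 100.0 * np.exp(-((x - 190.0) ** 2) / (2 * 50.0**2))
        prof = LineProfile(x, y, background_estimate=0.0)
        with pytest.raises(NoCrossingError, match="right"):
            measure_fwhm(prof)

    def test_affine_intensity_invariance(self):
        """Gain and offset on the profile leave the FWHM unchanged."""
        base = gaussian_profile(120.0)
        scaled = LineProfile(base.positions_nm,
                             7.0 * base.intensities + 40.0,
                             background_estimate=40.0)
        assert measure_fwhm(scaled) == pytest.approx(measure_fwhm(base),
                                                     rel=1e-9)

    @pytest.mark.parametrize("fwhm", [60.0, 80.0, 100.0, 120.0, 160.0, 240.0])
    def test_end_to_end_bias_on_noiseless_puncta(self, fwhm):
        """Segmentation + profile + half-max reading recovers the true FWHM
        of noiseless Gaussian puncta within 3% (mean over subpixel
        placements)."""
        rng = np.random.default_rng(int(fwhm))
        errs = []
        for _ in range(12):
            scene = make_single_punctum_scene(
                1280 + rng.uniform(-10, 10), 1280 + rng.uniform(-10, 10),
                fwhm_nm=fwhm)
            img, ps = segmented_single_punctum(scene)
            measure_puncta_fwhm(img, ps, smooth_window=1)
            errs.append(ps.puncta[0].fwhm_nm - fwhm)
        assert abs(np.mean(errs)) / fwhm <= 0.03

    def test_scale_equivariance(self):
        """Doubling pixel size and punctum width doubles the estimate."""
        scene1 = make_single_punctum_scene(1283.0, 1287.0, fwhm_nm=100.0)
        img1, ps1 = segmented_single_punctum(scene1)
        measure_puncta_fwhm(img1, ps1, smooth_window=1)

        from azpunct.simgen import GroundTruthPunctum, MaskSpec, SceneSpec
        spec2 = MaskSpec("rectangle", {"center_x_nm": 2560,
                                       "center_y_nm": 2560,
                                       "width_nm": 4800, "height_nm": 4800})
        scene2 = SceneSpec(128, 128, 40.0, ["ch"],
                           [GroundTruthPunctum(0, "ch", 2566.0, 2574.0, 150.0,
                                               200.0)],
                           spec2, background_level=0.0, read_noise_sd=0.0)
        img2 = render_channel(scene2, "ch")
        mask2 = realize_mask(spec2, 128, 128, 40.0)
        ps2 = segment_puncta(img2, 0.05 * img2.pixels.max(), mask2)
        measure_puncta_fwhm(img2, ps2, smooth_window=1)
        assert ps2.puncta[0].fwhm_nm == pytest.approx(
            2 * ps1.puncta[0].fwhm_nm, rel=0.01)


class TestIntensityAndDensity:
    def _uniform_punctum(self, full_mask):
        img = np.zeros((128, 128))
        img[10:12, 10:15] = 50.0  # 10 px at 50
        return image_of(img)

    def test_intensity_per_area_arithmetic(self):
        """10 px at intensity 50 inside a 2 µm² mask: 500 / 2 = 250."""
        img = np.zeros((128, 128))
        img[60:62, 40:45] = 50.0
        from azpunct.core import SynapseMask
        mask = np.zeros((128, 128), bool)
        mask[50:100, 30:130] = True  # 50*100 px -> 2.0 um^2 at 20 nm
        mask = SynapseMask(mask[:, :128] & True, 20.0)
        mask.pixels[:] = False
        mask.pixels[50:100, 28:128] = True
        image = image_of(img)
        ps = segment_puncta(image, 25.0, mask, min_size_px=1)
        assert mask.area_um2 == pytest.approx(2.0)
        assert intensity_per_area(image, ps, mask) == pytest.approx(250.0)

    def test_zero_puncta_zero_intensity(self, full_mask):
        image = image_of(np.zeros((128, 128)))
        ps = segment_puncta(image, 10.0, full_mask)
        assert intensity_per_area(image, ps, full_mask) == 0.0

    def test_intensity_linearity(self, full_mask):
        img = np.zeros((128, 128))
        img[60:64, 60:64] = 80.0
        im1 = image_of(img)
        im2 = image_of(2 * img)
        ps = segment_puncta(im1, 40.0, full_mask)
        assert intensity_per_area(im2, ps, full_mask) == pytest.approx(
            2 * intensity_per_area(im1, ps, full_mask))
        rec = ps.puncta[0]
        assert intensity_per_punctum(im2, rec, ps.label_image) == pytest.approx(
            2 * intensity_per_punctum(im1, rec, ps.label_image))

    def test_intensity_per_punctum_mean(self, full_mask):
        img = np.zeros((128, 128))
        img[30, 30] = 40.0
        img[30, 31] = 60.0
        image = image_of(img)
        ps = segment_puncta(image, 10.0, full_mask, min_size_px=1)
        assert intensity_per_punctum(image, ps.puncta[0],
                                     ps.label_image) == pytest.approx(50.0)

    def test_intensity_per_punctum_missing_label(self, full_mask):
        image = image_of(np.zeros((128, 128)))
        rec = PunctumRecord(99, 0, 0, 1, 1, 1, 1, 1)
        with pytest.raises(KeyError):
            intensity_per_punctum(image, rec, np.zeros((128, 128), int))

    def test_density_arithmetic(self, full_mask):
        """12 puncta over 2 µm²: 6 puncta/µm²; invariant to intensity."""
        img = np.zeros((128, 128))
        for k in range(12):
            r, c = 20 + 8 * k, 64
            img[r:r + 2, c:c + 2] = 100.0
        from azpunct.core import SynapseMask
        mask = np.zeros((128, 128), bool)
        mask[0:50, 0:100] = True  # 2.0 um^2
        mask = SynapseMask(mask, 20.0)
        image = image_of(img)
        ps = segment_puncta(image, 50.0, mask, min_size_px=1)
        n_inside = len(ps)
        assert puncta_density(ps, mask) == pytest.approx(n_inside / 2.0)
        ps2 = segment_puncta(image_of(5 * img), 5 * 50.0, mask, min_size_px=1)
        assert puncta_density(ps2, mask) == puncta_density(ps, mask)


def _record(label, fwhm=100.0, border=False):
    return PunctumRecord(label, 0, 0, 4, 0.0016, 10, 10, 40, fwhm_nm=fwhm,
                         border_flag=border)


class TestRepresentativeSampling:
    def _hierarchy(self, n_animals=5, n_synapses=5, n_puncta=14):
        label = [0]

        def rec():
            label[0] += 1
            return _record(label[0])

        return {a: {s: [rec() for _ in range(n_puncta)]
                    for s in range(n_synapses)}
                for a in range(n_animals)}

    def test_full_design_yields_250(self):
        """10 puncta per synapse, 5 synapses per animal, 5 animals: 250."""
        sample = sample_representative_puncta(self._hierarchy(), 10, seed=1)
        assert len(sample) == 250

    def test_short_synapse_takes_all_with_warning(self):
        h = self._hierarchy(1, 1, 6)
        with pytest.warns(UserWarning, match="only 6"):
            sample = sample_representative_puncta(h, 10, seed=1)
        assert len(sample) == 6

    def test_border_and_unmeasured_excluded(self):
        h = {0: {0: [_record(1), _record(2, border=True),
                     _record(3, fwhm=None), _record(4)]}}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sample = sample_representative_puncta(h, 10, seed=0)
        assert {p.label for p in sample} == {1, 4}

    def test_same_seed_same_sample(self):
        h = self._hierarchy()
        s1 = sample_representative_puncta(h, 10, seed=42)
        s2 = sample_representative_puncta(h, 10, seed=42)
        assert [p.label for p in s1] == [p.label for p in s2]

    def test_empty_hierarchy_rejected(self):
        with pytest.raises(ValueError):
            sample_representative_puncta({}, 10, seed=0)
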