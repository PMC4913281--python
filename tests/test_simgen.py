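"""Synthetic scene generator: geometry, rendering, noise, mask, ground truth."""

import math

import numpy as np
import pytest

from azpunct.core import FWHM_PER_SIGMA, MaskError, PlacementError
from azpunct.simgen import (
    GroundTruthPunctum,
    MaskSpec,
    MotifSpec,
    SceneConfig,
    SceneSpec,
    apply_noise,
    build_scene,
    read_ground_truth,
    realize_mask,
    render_channel,
    write_ground_truth,
)


class TestBuildScene:
    def test_single_sandwich_geometry(self):
        """One sandwich: two flanks ~100 nm apart in the flank channel and one
        center punctum of the partner channel at their midpoint."""
        cfg = SceneConfig(motifs=(MotifSpec("sandwich", 1, jitter_sd_nm=0.0),),
                          rng_seed=3)
        scene = build_scene(cfg)
        flanks = [p for p in scene.puncta if p.motif_role == "flank"]
        centers = [p for p in scene.puncta if p.motif_role == "center"]
        assert len(flanks) == 2 and len(centers) == 1
        assert all(p.channel == "piccolo" for p in flanks)
        assert centers[0].channel == "bassoon"
        sep = math.hypot(flanks[0].x_nm - flanks[1].x_nm,
                         flanks[0].y_nm - flanks[1].y_nm)
        assert sep == pytest.approx(100.0, abs=1e-9)
        mx = (flanks[0].x_nm + flanks[1].x_nm) / 2
        my = (flanks[0].y_nm + flanks[1].y_nm) / 2
        assert centers[0].x_nm == pytest.approx(mx, abs=1e-9)
        assert centers[0].y_nm == pytest.approx(my, abs=1e-9)

    def test_tandem_sandwich_alternates(self):
        cfg = SceneConfig(motifs=(MotifSpec("tandem_sandwich", 1,
                                            jitter_sd_nm=0.0),), rng_seed=3)
        scene = build_scene(cfg)
        assert len(scene.puncta_in_channel("piccolo")) == 3
        assert len(scene.puncta_in_channel("bassoon")) == 2

    def test_no_motifs_gives_empty_scene(self):
        scene = build_scene(SceneConfig(motifs=(), rng_seed=0))
        assert scene.puncta == []

    def test_deterministic_given_seed(self):
        cfg = SceneConfig(motifs=(MotifSpec("coloc_pair", 10),), rng_seed=7)
        a, b = build_scene(cfg), build_scene(cfg)
        assert a == b

    def test_infeasible_placement_raises(self):
        cfg = SceneConfig(motifs=(MotifSpec("solitary", 500,
                                            channels=("piccolo",)),),
                          min_motif_spacing_nm=600.0, rng_seed=0)
        with pytest.raises(PlacementError, match="min_motif_spacing_nm"):
            build_scene(cfg)

    def test_puncta_stay_inside_mask(self):
        cfg = SceneConfig(motifs=(MotifSpec("sandwich", 4),), rng_seed=11)
        scene = build_scene(cfg)
        mask = realize_mask(scene.mask_spec, scene.width_px, scene.height_px,
                            scene.pixel_size_nm)
        for p in scene.puncta:
            r = int(p.y_nm / scene.pixel_size_nm)
            c = int(p.x_nm / scene.pixel_size_nm)
            assert mask.pixels[r, c]

    def test_poisson_counts_vary_but_are_seeded(self):
        cfg = SceneConfig(motifs=(MotifSpec("solitary", 8,
                                            channels=("piccolo",)),),
                          count_distribution="poisson", rng_seed=1)
        counts = {len(build_scene(
            SceneConfig(motifs=cfg.motifs, count_distribution="poisson",
                        rng_seed=s)).puncta) for s in range(6)}
        assert len(counts) > 1
        assert len(build_scene(cfg).puncta) == len(build_scene(cfg).puncta)


class TestRenderChannel:
    def test_peak_value_on_pixel_center(self, single_punctum_factory):
        """A punctum centred exactly on a pixel centre renders its amplitude
        at that pixel (Gaussian maximum)."""
        scene = single_punctum_factory(1290.0, 1290.0, amplitude=100.0)
        img = render_channel(scene, "ch")
        assert img.pixels.max() == pytest.approx(100.0, rel=1e-12)
        assert img.pixels[64, 64] == pytest.approx(100.0, rel=1e-12)

    def test_total_flux_matches_gaussian_integral(self, single_punctum_factory):
        """Image sum approximates A * 2*pi*sigma^2 / px^2 (dense-integration
        oracle of the 2D Gaussian)."""
        amp, fwhm, px = 100.0, 100.0, 20.0
        scene = single_punctum_factory(1283.0, 1287.0, amplitude=amp,
                                       fwhm_nm=fwhm)
        img = render_channel(scene, "ch")
        sigma = fwhm / FWHM_PER_SIGMA
        expected = amp * 2 * math.pi * sigma**2 / px**2
        assert img.pixels.sum() == pytest.approx(expected, rel=5e-3)

    def test_empty_scene_renders_background(self):
        scene = SceneSpec(32, 32, 20.0, ["ch"], [],
                          MaskSpec("rectangle",
                                   {"center_x_nm": 320, "center_y_nm": 320,
                                    "width_nm": 600, "height_nm": 600}),
                          background_level=5.0)
        img = render_channel(scene, "ch")
        assert np.all(img.pixels == 5.0)

    def test_unknown_channel_raises(self, single_punctum_factory):
        with pytest.raises(ValueError, match="unknown channel"):
            render_channel(single_punctum_factory(1280, 1280), "nope")

    def test_rendering_is_linear_in_amplitude(self, single_punctum_factory):
        base = single_punctum_factory(1283.0, 1287.0, amplitude=80.0,
                                      background=5.0)
        scaled = single_punctum_factory(1283.0, 1287.0, amplitude=240.0,
                                        background=5.0)
        a = render_channel(base, "ch").pixels
        b = render_channel(scaled, "ch").pixels
        np.testing.assert_allclose(b - 5.0, 3.0 * (a - 5.0), rtol=1e-9,
                                   atol=1e-12)


class TestApplyNoise:
    def test_zero_image_zero_noise(self, single_punctum_factory):
        scene = single_punctum_factory(1280, 1280, amplitude=1e-12)
        img = render_channel(scene, "ch")
        out = apply_noise(img, 0.0, seed=1)
        assert np.all(out.pixels == 0.0)

    def test_same_seed_is_bit_identical(self, rendered_punctum):
        img, _, _ = rendered_punctum
        a = apply_noise(img, 1.0, seed=42)
        b = apply_noise(img, 1.0, seed=42)
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_negative_input_rejected(self, full_mask):
        from azpunct.core import ImageChannel
        img = ImageChannel(np.zeros((16, 16)), 20.0, "ch")
        img.pixels[0, 0] = -1.0  # bypass constructor validation deliberately
        with pytest.raises(ValueError, match="nonnegative"):
            apply_noise(img, 0.0, seed=0)


def test_poisson_sample_mean_close_to_rate():
    """Uniform image of 10000: the noisy sample mean over >= 10^4 pixels is
    within 1% of the rate (law of large numbers for Poisson counts)."""
    from azpunct.core import ImageChannel
    img = ImageChannel(np.full((128, 128), 10000.0), 20.0, "ch")
    out = apply_noise(img, 0.0, seed=3)
    assert out.pixels.mean() == pytest.approx(10000.0, rel=0.01)


class TestRealizeMask:
    def test_rectangle_area_arithmetic(self):
        spec = MaskSpec("rectangle", {"center_x_nm": 1280, "center_y_nm": 1280,
                                      "width_nm": 1000, "height_nm": 2000})
        mask = realize_mask(spec, 128, 128, 20.0)
        assert mask.area_um2 == pytest.approx(2.0, rel=1e-9)

    def test_ellipse_band_matches_per_pixel_oracle(self):
        spec = MaskSpec("ellipse_band", {"center_x_nm": 1280,
                                         "center_y_nm": 1200,
                                         "outer_a_nm": 900, "outer_b_nm": 600,
                                         "band_fraction": 0.5})
        mask = realize_mask(spec, 128, 128, 20.0)
        count = 0
        for r in range(128):
            for c in range(128):
                x, y = (c + 0.5) * 20.0, (r + 0.5) * 20.0
                q = ((x - 1280) / 900) ** 2 + ((y - 1200) / 600) ** 2
                count += (q <= 1.0) and (q >= 0.25)
        assert int(mask.pixels.sum()) == count

    def test_mask_outside_image_raises(self):
        spec = MaskSpec("rectangle", {"center_x_nm": 99999,
                                      "center_y_nm": 99999,
                                      "width_nm": 100, "height_nm": 100})
        with pytest.raises(MaskError, match="empty"):
            realize_mask(spec, 64, 64, 20.0)

    def test_fold_lines_reduce_area(self):
        base = MaskSpec("rectangle", {"center_x_nm": 1280, "center_y_nm": 1280,
                                      "width_nm": 2000, "height_nm": 2000})
        striped = MaskSpec("rectangle", dict(base.params),
                           fold_line_spacing_nm=400.0)
        full = realize_mask(base, 128, 128, 20.0)
        folds = realize_mask(striped, 128, 128, 20.0)
        assert 0 < folds.pixels.sum() < full.pixels.sum()


class TestGroundTruthRoundTrip:
    def test_roundtrip_identity(self, tmp_path):
        cfg = SceneConfig(motifs=(MotifSpec("sandwich", 2),
                                  MotifSpec("solitary", 1,
                                            channels=("bassoon",))),
                          rng_seed=5)
        scene = build_scene(cfg)
        path = tmp_path / "gt.csv"
        write_ground_truth(scene, path)
        back = read_ground_truth(path)
        assert back.width_px == scene.width_px
        assert back.channels == scene.channels
        assert len(back.puncta) == len(scene.puncta)
        for p, q in zip(scene.puncta, back.puncta):
            assert q.punctum_id == p.punctum_id
            assert q.channel == p.channel
            assert q.motif_id == p.motif_id
            assert q.motif_role == p.motif_role
            assert abs(q.x_nm - p.x_nm) < 1e-3
            assert abs(q.y_nm - p.y_nm) < 1e-3
            assert abs(q.fwhm_true_nm - p.fwhm_true_nm) < 1e-3

    def test_csv_row_count(self, tmp_path):
        cfg = SceneConfig(motifs=(MotifSpec("sandwich", 1),), rng_seed=5)
        path = tmp_path / "gt.csv"
        write_ground_truth(build_scene(cfg), path)
        assert len(path.read_text().strip().splitlines()) == 4  # header + 3

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "gt.csv"
        path.write_text("punctum_id,channel,x_nm\n0,ch,1\n")
        (tmp_path / "gt.scene.json").write_text("{}")
        with pytest.raises(ValueError, match="y_nm"):
            read_ground_truth(path)

    def test_negative_fwhm_rejected(self, tmp_path):
        cfg = SceneConfig(motifs=(MotifSpec("solitary", 1,
                                            channels=("piccolo",)),),
                          rng_seed=1)
        path = tmp_path / "gt.csv"
        write_ground_truth(build_scene(cfg), path)
        text = path.read_text()
        lines = text.splitlines()
        parts = lines[1].split(",")
        parts[5] = "-50.0"
        lines[1] = ",".join(parts)
        path.write_text("\n".join(lines))
        with pytest.raises(ValueError, match="fwhm_true_nm"):
            read_ground_truth(path)


def test_punctum_validation():
    with pytest.raises(ValueError):
        GroundTruthPunctum(0, "ch", 0, 0, amplitude=-1, fwhm_true_nm=100)
    with pytest.raises(ValueError):
        GroundTruthPunctum(0, "ch", 0, 0, amplitude=1, fwhm_true_nm=0)
    with pytest.raises(ValueError, match="motif_id"):
        GroundTruthPunctum(0, "ch", 0, 0, 1, 100, motif_id=None,
                           motif_role="center")
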