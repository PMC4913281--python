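"""Self-validation protocols run against simulator ground truth.

Each function here executes one verification protocol end-to-end at a
stated problem size — oracle equivalence for the threshold search, FWHM
parameter recovery, counting exactness, colocalization fidelity, sandwich
detection, statistical calibration, raw-versus-deconvolved similarity and
output determinism — and returns plain numbers.  The protocols are used by
the test suite and by ``scripts/acceptance.py``.
"""

from __future__ import annotations

import tempfile
import warnings
from pathlib import Path

import numpy as np
from scipy import stats as sps

from .coloc import associate_puncta, detect_sandwich
from .evaluate import (
    match_to_truth,
    score_category_fidelity,
    score_sandwich_detection,
)
from .metrics import measure_puncta_fwhm
from .pipeline import GroupConfig, PipelineConfig, process_synapse, run_pipeline
from .segment import (
    NoObjectPeakError,
    auto_threshold_light,
    deconvolve,
    segment_puncta,
    trough_threshold,
)
from .simgen import (
    GroundTruthPunctum,
    MaskSpec,
    MotifSpec,
    SceneConfig,
    SceneSpec,
    apply_noise,
    build_scene,
    realize_mask,
    render_channel,
    render_noisy_channel,
)
from .stats import empirical_type1_error, unpaired_ttest


def exhaustive_trough_scan(counts) -> tuple[int, int, int] | None:
    """Independent brute-force reference for the histogram-trough search.

    Scans every bin: modal background bin; strict local maxima with virtual
    zero-count neighbours beyond the ends and plateaus taken at their
    dimmest bin; object peak = highest-count maximum brighter than the
    background (ties dimmest); trough = dimmest minimal-count bin strictly
    between the peaks (the object bin itself when they are adjacent).
    """
    counts = [float(c) for c in counts]
    n = len(counts)
    background = counts.index(max(counts))
    maxima = []
    for i in range(n):
        if i > 0 and counts[i - 1] == counts[i]:
            continue  # not the dimmest bin of its plateau
        j = i
        while j + 1 < n and counts[j + 1] == counts[i]:
            j += 1
        left = counts[i - 1] if i > 0 else -1.0
        right = counts[j + 1] if j + 1 < n else -1.0
        if left < counts[i] and right < counts[i]:
            maxima.append(i)
    cands = [m for m in maxima if m > background]
    if not cands:
        return None
    top = max(counts[m] for m in cands)
    obj = min(m for m in cands if counts[m] == top)
    between = range(background + 1, obj)
    if not between:
        return background, obj, obj
    low = min(counts[i] for i in between)
    trough = min(i for i in between if counts[i] == low)
    return background, obj, trough


def threshold_oracle_agreement(seed: int, n_histograms: int = 100) -> dict:
    """Fraction of randomized bimodal histograms on which the trough search
    agrees exactly with the exhaustive scan."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_histograms):
        n = int(rng.integers(8, 80))
        counts = rng.integers(0, 25, size=n).astype(float)
        b = int(rng.integers(0, n - 2))
        o = int(rng.integers(b + 1, n))
        counts[b] = 1000.0
        counts[o] += 400.0
        edges = np.arange(n + 1, dtype=float)
        want = exhaustive_trough_scan(counts)
        try:
            res = trough_threshold(counts, edges)
            got = (res.background_peak_bin, res.object_peak_bin,
                   res.trough_bin)
        except NoObjectPeakError:
            got = None
        agree += got == want
    return {"agreement_pct": 100.0 * agree / n_histograms, "n": n_histograms}


def _isolated_punctum_scene(x, y, amplitude, fwhm, background, read_noise,
                            size_px=128):
    half = size_px * 20.0 / 2
    spec = MaskSpec("rectangle", {"center_x_nm": half, "center_y_nm": half,
                                  "width_nm": 2 * half - 160,
                                  "height_nm": 2 * half - 160})
    return SceneSpec(size_px, size_px, 20.0, ["ch"],
                     [GroundTruthPunctum(0, "ch", x, y, amplitude, fwhm)],
                     spec, background_level=background,
                     read_noise_sd=read_noise)


def fwhm_recovery(seed: int, widths=(60.0, 80.0, 100.0, 120.0, 160.0, 240.0),
                  reps: int = 12, n_noisy: int = 250) -> dict:
    """FWHM estimator bias on noiseless Gaussian puncta per width, and mean
    recovery over ``n_noisy`` shot-noise-limited puncta at peak SNR ~ 10."""
    rng = np.random.default_rng(seed)
    biases = {}
    for fwhm in widths:
        errs = []
        for _ in range(reps):
            scene = _isolated_punctum_scene(1280 + rng.uniform(-10, 10),
                                            1280 + rng.uniform(-10, 10),
                                            150.0, fwhm, 0.0, 0.0)
            img = render_channel(scene, "ch")
            mask = realize_mask(scene.mask_spec, 128, 128, 20.0)
            ps = segment_puncta(img, 0.05 * img.pixels.max(), mask)
            measure_puncta_fwhm(img, ps, smooth_window=1)
            errs.append(ps.puncta[0].fwhm_nm - fwhm)
        biases[fwhm] = 100.0 * float(np.mean(errs)) / fwhm
    true_fwhm = 100.0
    vals = []
    while len(vals) < n_noisy:
        scene = _isolated_punctum_scene(640 + rng.uniform(-10, 10),
                                        640 + rng.uniform(-10, 10),
                                        120.0, true_fwhm, 5.0, 1.0,
                                        size_px=64)
        img = apply_noise(render_channel(scene, "ch"), 1.0,
                          int(rng.integers(2**31)))
        mask = realize_mask(scene.mask_spec, 64, 64, 20.0)
        try:
            th = auto_threshold_light(img, mask)
        except NoObjectPeakError:
            continue
        ps = segment_puncta(img, th.threshold, mask)
        measure_puncta_fwhm(img, ps)
        for lab in match_to_truth(ps, scene.puncta):
            f = ps.by_label(lab).fwhm_nm
            if f is not None:
                vals.append(f)
    vals = np.asarray(vals[:n_noisy])
    return {
        "max_abs_bias_pct": float(max(abs(b) for b in biases.values())),
        "bias_pct_by_width": biases,
        "noisy_mean_fwhm_nm": float(vals.mean()),
        "noisy_mean_error_pct": float(100.0 * (vals.mean() - true_fwhm)
                                      / true_fwhm),
        "n_noisy": int(vals.size),
    }


def counting_exactness(seed: int, n_scenes: int = 50,
                       puncta_per_scene: int = 12) -> dict:
    """Punctum-count recovery on noisy scenes of isolated puncta with
    centroid separations >= 300 nm, and density = count/area exactness."""
    exact = 0
    density_exact = True
    for k in range(n_scenes):
        cfg = SceneConfig(
            motifs=(MotifSpec("solitary", puncta_per_scene,
                              channels=("bassoon",)),),
            channels=("bassoon",), min_motif_spacing_nm=350.0,
            rng_seed=seed + k)
        scene = build_scene(cfg)
        mask = realize_mask(scene.mask_spec, scene.width_px, scene.height_px,
                            scene.pixel_size_nm)
        img = render_noisy_channel(scene, "bassoon")
        th = auto_threshold_light(img, mask)
        ps = segment_puncta(img, th.threshold, mask)
        exact += len(ps) == len(scene.puncta)
        from .metrics import puncta_density
        density_exact &= (puncta_density(ps, mask)
                          == len(ps) / mask.area_um2)
    return {"exact_scenes": int(exact), "n_scenes": n_scenes,
            "density_matches_count_over_area": bool(density_exact)}


COLOC_SCENE_MOTIFS = (
    MotifSpec("sandwich", 5),
    MotifSpec("coloc_pair", 3),
    MotifSpec("solitary", 3, channels=("piccolo",)),
    MotifSpec("solitary", 3, channels=("bassoon",)),
)


def coloc_fidelity(seed: int, n_scenes: int = 50) -> dict:
    """Category fidelity and sandwich detection on mixed-motif scenes at
    the measured active-zone geometry (100 nm flank separation, ~100-126 nm
    FWHM, 20 nm pixels), run through the full default pipeline stages."""
    config = PipelineConfig(seed=seed, groups=(GroupConfig("x", 1, 1),))
    n_scored = n_matched = 0
    n_true = n_hits = n_rec = n_false = 0
    for k in range(n_scenes):
        cfg = SceneConfig(motifs=COLOC_SCENE_MOTIFS, rng_seed=seed + k)
        scene = build_scene(cfg)
        mask = realize_mask(scene.mask_spec, scene.width_px, scene.height_px,
                            scene.pixel_size_nm)
        images = {ch: render_noisy_channel(scene, ch)
                  for ch in scene.channels}
        puncta, _, _ = process_synapse(config, images, mask)
        graph = associate_puncta(puncta["bassoon"], puncta["piccolo"],
                                 config.association_radius_nm)
        fid = score_category_fidelity(scene, puncta["bassoon"],
                                      puncta["piccolo"], graph)
        n_scored += fid.n_scored
        n_matched += fid.n_matched
        hits = detect_sandwich(puncta["piccolo"], puncta["bassoon"], graph)
        sc = score_sandwich_detection(scene, puncta["bassoon"], hits)
        n_true += sc.n_true
        n_hits += sc.n_hits
        n_rec += sc.n_recovered
        n_false += sc.n_false
    return {
        "category_match_pct": 100.0 * n_matched / n_scored,
        "n_scored_puncta": int(n_scored),
        "sandwich_recall_pct": 100.0 * n_rec / n_true,
        "sandwich_fdr_pct": 100.0 * n_false / n_hits if n_hits else 0.0,
        "n_true_sandwiches": int(n_true),
        "n_scenes": n_scenes,
    }


def stats_oracle(seed: int, n_null: int = 1000) -> dict:
    """Pooled t on the documented example lists plus null calibration."""
    r = unpaired_ttest([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
    rate = empirical_type1_error(n_null, 25, seed)
    return {"t_statistic": float(r.t_statistic),
            "df": float(r.degrees_of_freedom),
            "p_value": float(r.p_value),
            "type1_error": float(rate),
            "n_null": n_null}


def raw_vs_deconvolved_similarity(seed: int, n_scenes: int = 30,
                                  iterations: int = 10) -> dict:
    """Spearman rank correlation between raw-image and deconvolved-image
    quantification across scenes: per-synapse puncta density and mean
    per-punctum intensity.

    Scene brightness varies several-fold (log-uniformly) from scene to
    scene, as staining intensity does between synapses, so the vectors
    carry a real ordering for the rank correlation to preserve.
    """
    dens = {"raw": [], "dec": []}
    inten = {"raw": [], "dec": []}
    rng = np.random.default_rng(seed)
    for k in range(n_scenes):
        n_pairs = int(rng.integers(5, 12))
        n_solo = int(rng.integers(3, 8))
        amp_lo = float(np.exp(rng.uniform(np.log(60.0), np.log(350.0))))
        cfg = SceneConfig(
            motifs=(MotifSpec("coloc_pair", n_pairs),
                    MotifSpec("solitary", n_solo, channels=("bassoon",))),
            amplitude_range=(amp_lo, 1.3 * amp_lo),
            rng_seed=seed + 1000 + k)
        scene = build_scene(cfg)
        mask = realize_mask(scene.mask_spec, scene.width_px, scene.height_px,
                            scene.pixel_size_nm)
        img = render_noisy_channel(scene, "bassoon")
        for key, image in (("raw", img),
                           ("dec", deconvolve(img, 100.0, iterations))):
            th = auto_threshold_light(image, mask)
            ps = segment_puncta(image, th.threshold, mask)
            dens[key].append(len(ps) / mask.area_um2)
            inten[key].append(float(np.mean([p.mean_intensity
                                             for p in ps.puncta])))
    rho_d = float(sps.spearmanr(dens["raw"], dens["dec"]).statistic)
    rho_i = float(sps.spearmanr(inten["raw"], inten["dec"]).statistic)
    return {"spearman_density": rho_d, "spearman_intensity": rho_i,
            "n_scenes": n_scenes, "iterations": iterations}


def group_comparison_demo(seed: int, n_animals: int = 5,
                          synapses_per_animal: int = 5) -> dict:
    """Adult-versus-aged two-group study through the full pipeline.

    The aged group loses roughly a third of its Bassoon-containing motifs
    while Piccolo content stays comparable — the selective degeneration
    pattern — and the report's pooled t-tests on per-synapse density are
    returned for both proteins.
    """
    adult = {"motifs": [
        {"motif_type": "sandwich", "count": 5},
        {"motif_type": "coloc_pair", "count": 3},
        {"motif_type": "solitary", "count": 3, "channels": ["piccolo"]},
        {"motif_type": "solitary", "count": 3, "channels": ["bassoon"]}]}
    aged = {"motifs": [
        {"motif_type": "sandwich", "count": 3},
        {"motif_type": "coloc_pair", "count": 2},
        {"motif_type": "solitary", "count": 7, "channels": ["piccolo"]},
        {"motif_type": "solitary", "count": 2, "channels": ["bassoon"]}]}
    config = PipelineConfig(
        seed=seed,
        groups=(GroupConfig("adult", n_animals, synapses_per_animal,
                            scene=adult),
                GroupConfig("aged", n_animals, synapses_per_animal,
                            scene=aged)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bundle = run_pipeline(config)
    out: dict = {"n_synapses_per_group": n_animals * synapses_per_animal}
    for ch in ("bassoon", "piccolo"):
        row = bundle.group_stats[
            (bundle.group_stats.channel == ch)
            & (bundle.group_stats.measure == "density_per_um2")].iloc[0]
        out[f"{ch}_density_adult"] = float(row["adult_mean"])
        out[f"{ch}_density_aged"] = float(row["aged_mean"])
        out[f"{ch}_density_p"] = float(row["p_value"])
    return out


def determinism_check(seed: int) -> dict:
    """Two pipeline runs with the same config and seed produce byte-identical
    CSV outputs."""
    config = PipelineConfig(seed=seed,
                            groups=(GroupConfig("g", 1, 2),),
                            deconvolve_iterations=20)
    names = ("puncta.csv", "synapse_summary.csv", "coloc_categories.csv",
             "sandwich_hits.csv", "group_stats.csv", "manifest.json")
    with tempfile.TemporaryDirectory() as tmp:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            run_pipeline(config, Path(tmp) / "a")
            run_pipeline(config, Path(tmp) / "b")
        identical = all((Path(tmp) / "a" / n).read_bytes()
                        == (Path(tmp) / "b" / n).read_bytes() for n in names)
    return {"identical": bool(identical), "n_files": len(names)}
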