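"""End-to-end orchestration: simulate or load, segment, measure, compare.

A pipeline run processes a two-group study (e.g. adult vs aged) of
simulated synapses, or a list of image files, through the full chain:

    simulate/load -> (optional) deconvolve -> auto-threshold -> segment
    -> per-punctum metrics -> hierarchical sampling -> colocalization
    -> group statistics

and writes per-punctum, per-synapse, category, sandwich-hit and
group-comparison CSV tables plus a JSON manifest of every parameter and
seed.  Identical configuration and seed give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as azio
from .coloc import (
    associate_puncta,
    categorize_bassoon_vgcc,
    categorize_piccolo_bassoon,
    detect_sandwich,
    normalize_category_counts,
    DEFAULT_ASSOCIATION_RADIUS_NM,
    DEFAULT_SANDWICH_MAX_SEP_NM,
    DEFAULT_SANDWICH_MIN_ANGLE_DEG,
    DEFAULT_SANDWICH_MIN_SEP_NM,
)
from .core import (
    ConfigError,
    ImageChannel,
    NoObjectPeakError,
    PunctaSet,
    SynapseMask,
)
from .metrics import (
    intensity_per_area,
    measure_puncta_fwhm,
    puncta_density,
    sample_representative_puncta,
)
from .segment import (
    DEFAULT_MIN_SIZE_PX,
    DEFAULT_N_BINS,
    auto_threshold_light,
    deconvolve,
    segment_puncta,
)
from .simgen import (
    MaskSpec,
    MotifSpec,
    SceneConfig,
    build_scene,
    realize_mask,
    render_noisy_channel,
)
from .stats import summarize_group, unpaired_ttest

log = logging.getLogger("azpunct.pipeline")

DEFAULT_DECONV_ITERATIONS = 80
DEFAULT_PSF_FWHM_NM = 100.0


@dataclass
class GroupConfig:
    """One study group: how many units to image and what the scenes contain."""

    name: str
    n_animals: int = 5
    synapses_per_animal: int = 5
    scene: dict = field(default_factory=dict)  # SceneConfig field overrides


@dataclass
class PipelineConfig:
    seed: int = 0
    channels: tuple[str, ...] = ("piccolo", "bassoon")
    scheme: str | None = "piccolo_bassoon"
    groups: tuple[GroupConfig, ...] = ()
    inputs: tuple[dict, ...] = ()  # file mode: image/mask paths per synapse
    deconvolve_enabled: bool = True
    deconvolve_iterations: int = DEFAULT_DECONV_ITERATIONS
    psf_fwhm_nm: float = DEFAULT_PSF_FWHM_NM
    split_touching: bool | None = None  # default: follow deconvolve_enabled
    n_bins: int = DEFAULT_N_BINS
    min_size_px: int = DEFAULT_MIN_SIZE_PX
    association_radius_nm: float = DEFAULT_ASSOCIATION_RADIUS_NM
    sandwich_min_sep_nm: float = DEFAULT_SANDWICH_MIN_SEP_NM
    sandwich_max_sep_nm: float = DEFAULT_SANDWICH_MAX_SEP_NM
    sandwich_min_angle_deg: float = DEFAULT_SANDWICH_MIN_ANGLE_DEG
    puncta_per_synapse: int = 10

    def __post_init__(self) -> None:
        if self.scheme not in (None, "piccolo_bassoon", "bassoon_vgcc"):
            raise ConfigError(f"unknown scheme {self.scheme!r}")
        if not self.groups and not self.inputs:
            raise ConfigError("config needs either 'groups' (simulation) or "
                              "'inputs' (image files)")
        if self.groups and self.inputs:
            raise ConfigError("'groups' and 'inputs' are mutually exclusive")
        for inp in self.inputs:
            if "mask" not in inp:
                raise ConfigError("input entry is missing the 'mask' field")
            if "images" not in inp:
                raise ConfigError("input entry is missing the 'images' field")

    @property
    def effective_split(self) -> bool:
        if self.split_touching is None:
            return self.deconvolve_enabled
        return self.split_touching


def config_from_dict(d: dict) -> PipelineConfig:
    d = dict(d)
    groups = tuple(GroupConfig(**g) for g in d.pop("groups", []))
    inputs = tuple(d.pop("inputs", []))
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(d) - known
    if unknown:
        raise ConfigError(f"unknown configuration fields: {sorted(unknown)}")
    if "channels" in d:
        d["channels"] = tuple(d["channels"])
    return PipelineConfig(groups=groups, inputs=inputs, **d)


def load_config(path: str | Path) -> PipelineConfig:
    return config_from_dict(json.loads(Path(path).read_text()))


def _scene_config(base: dict, channels: tuple[str, ...], seed: int) -> SceneConfig:
    kw = dict(base)
    motifs = tuple(MotifSpec(**m) if isinstance(m, dict) else m
                   for m in kw.pop("motifs", ()))
    mask_spec = kw.pop("mask_spec", None)
    if isinstance(mask_spec, dict):
        mask_spec = MaskSpec(**mask_spec)
    if "fwhm_nm" in kw:
        kw["fwhm_nm"] = {k: tuple(v) for k, v in kw["fwhm_nm"].items()}
    return SceneConfig(channels=tuple(channels), motifs=motifs,
                       mask_spec=mask_spec, rng_seed=seed, **kw)


def default_motifs(channels: tuple[str, ...]) -> tuple[MotifSpec, ...]:
    """Default scene content for a channel pair.

    A Piccolo/Bassoon pair gets the sandwich-dominated composition seen at
    adult synapses; any other pair gets colocalized pairs plus solitary
    puncta (the Bassoon/VGCC-like arrangement); a single channel gets
    solitary puncta only.
    """
    if len(channels) < 2:
        return (MotifSpec("solitary", 12, channels=(channels[0],)),)
    lowered = {c.lower() for c in channels}
    if lowered == {"piccolo", "bassoon"}:
        return (
            MotifSpec("sandwich", 5),
            MotifSpec("coloc_pair", 3),
            MotifSpec("solitary", 3, channels=("piccolo",)),
            MotifSpec("solitary", 3, channels=("bassoon",)),
        )
    a, b = channels[0], channels[1]
    return (
        MotifSpec("coloc_pair", 6, channels=(a, b)),
        MotifSpec("solitary", 3, channels=(a,)),
        MotifSpec("solitary", 3, channels=(b,)),
    )


@dataclass
class SynapseResult:
    group: str
    animal: int
    synapse: int
    mask: SynapseMask
    images: dict[str, ImageChannel]
    puncta: dict[str, PunctaSet]
    thresholds: dict[str, float]
    scene: object | None = None  # SceneSpec when simulated


@dataclass
class ReportBundle:
    puncta: pd.DataFrame
    synapses: pd.DataFrame
    categories: pd.DataFrame
    sandwich_hits: pd.DataFrame
    group_stats: pd.DataFrame
    manifest: dict
    results: list[SynapseResult]


def _derive_seed(*keys: int) -> int:
    return int(np.random.SeedSequence(list(keys)).generate_state(1)[0] % (2**31))


def process_synapse(config: PipelineConfig, images: dict[str, ImageChannel],
                    mask: SynapseMask) -> tuple[dict[str, PunctaSet],
                                                dict[str, float],
                                                dict[str, ImageChannel]]:
    """Deconvolve (optionally), threshold, segment and measure one synapse."""
    puncta: dict[str, PunctaSet] = {}
    thresholds: dict[str, float] = {}
    processed: dict[str, ImageChannel] = {}
    for ch, raw in images.items():
        img = raw
        if config.deconvolve_enabled and config.deconvolve_iterations > 0:
            img = deconvolve(raw, config.psf_fwhm_nm, config.deconvolve_iterations)
        processed[ch] = img
        try:
            threshold = auto_threshold_light(img, mask, config.n_bins).threshold
        except NoObjectPeakError:
            threshold = float(img.pixels.max())
        # degenerate-channel guard: a channel with no real puncta has a
        # noise-only histogram whose "trough" sits inside the background, so
        # nearly every masked pixel would be called object; score it empty
        if (img.pixels[mask.pixels] > threshold).mean() > 0.25:
            threshold = float(img.pixels.max())
        ps = segment_puncta(img, threshold, mask, config.min_size_px,
                            split_touching=config.effective_split)
        # punctum size is read off the unsharpened image so the FWHM is the
        # optical width, not the deconvolution residual
        measure_puncta_fwhm(raw, ps)
        puncta[ch] = ps
        thresholds[ch] = threshold
    return puncta, thresholds, processed


def _iter_simulated(config: PipelineConfig):
    for gi, group in enumerate(config.groups):
        for animal in range(group.n_animals):
            for synapse in range(group.synapses_per_animal):
                seed = _derive_seed(config.seed, gi, animal, synapse)
                base = dict(group.scene)
                if "motifs" not in base:
                    base["motifs"] = default_motifs(config.channels)
                # synapses vary biologically in content: motif counts are
                # Poisson around the group means unless overridden
                base.setdefault("count_distribution", "poisson")
                scene_cfg = _scene_config(base, config.channels, seed)
                scene = build_scene(scene_cfg)
                mask = realize_mask(scene.mask_spec, scene.width_px,
                                    scene.height_px, scene.pixel_size_nm)
                images = {ch: render_noisy_channel(scene, ch)
                          for ch in config.channels}
                yield group.name, animal, synapse, images, mask, scene


def _iter_files(config: PipelineConfig):
    for i, inp in enumerate(config.inputs):
        mask = azio.read_mask(inp["mask"], inp.get("pixel_size_nm"))
        images = {ch: azio.read_image(path, inp.get("pixel_size_nm"), ch)
                  for ch, path in inp["images"].items()}
        yield (inp.get("group", "all"), int(inp.get("animal", 0)),
               int(inp.get("synapse", i)), images, mask, None)


def run_pipeline(config: PipelineConfig,
                 out_dir: str | Path | None = None) -> ReportBundle:
    """Execute the full analysis and optionally write the report CSVs."""
    t_start = time.perf_counter()
    results: list[SynapseResult] = []
    source = _iter_simulated(config) if config.groups else _iter_files(config)
    for group, animal, synapse, images, mask, scene in source:
        t0 = time.perf_counter()
        puncta, thresholds, _ = process_synapse(config, images, mask)
        results.append(SynapseResult(group=group, animal=animal, synapse=synapse,
                                     mask=mask, images=images, puncta=puncta,
                                     thresholds=thresholds, scene=scene))
        log.info("synapse %s/%d/%d: %s in %.2fs", group, animal, synapse,
                 {ch: len(ps) for ch, ps in puncta.items()},
                 time.perf_counter() - t0)

    puncta_rows = []
    synapse_rows = []
    category_rows = []
    sandwich_rows = []

    # hierarchical FWHM sampling: per group and channel
    sampled_keys: set[tuple] = set()
    group_names = sorted({r.group for r in results})
    for group in group_names:
        for ch in config.channels:
            hierarchy: dict[int, dict[int, list]] = {}
            keys: dict[int, tuple] = {}
            for r in results:
                if r.group != group:
                    continue
                hierarchy.setdefault(r.animal, {})[r.synapse] = r.puncta[ch].puncta
            sampled = sample_representative_puncta(
                hierarchy, config.puncta_per_synapse,
                _derive_seed(config.seed, 7, group_names.index(group),
                             list(config.channels).index(ch)))
            for r in results:
                if r.group != group:
                    continue
                for p in r.puncta[ch].puncta:
                    if any(p is s for s in sampled):
                        sampled_keys.add((group, r.animal, r.synapse, ch, p.label))

    for r in results:
        for ch in config.channels:
            ps = r.puncta[ch]
            img = r.images[ch]
            for p in ps.puncta:
                puncta_rows.append({
                    "group": r.group, "animal": r.animal, "synapse": r.synapse,
                    "channel": ch, "label": p.label,
                    "centroid_x_nm": round(p.centroid_x_nm, 3),
                    "centroid_y_nm": round(p.centroid_y_nm, 3),
                    "area_px": p.area_px,
                    "area_um2": round(p.area_um2, 6),
                    "peak_intensity": round(p.peak_intensity, 3),
                    "mean_intensity": round(p.mean_intensity, 3),
                    "integrated_intensity": round(p.integrated_intensity, 3),
                    "fwhm_nm": None if p.fwhm_nm is None else round(p.fwhm_nm, 3),
                    "border_flag": p.border_flag,
                    "sampled": (r.group, r.animal, r.synapse, ch, p.label)
                               in sampled_keys,
                })
            synapse_rows.append({
                "group": r.group, "animal": r.animal, "synapse": r.synapse,
                "channel": ch,
                "mask_area_um2": round(r.mask.area_um2, 6),
                "threshold": round(r.thresholds[ch], 6),
                "n_puncta": len(ps),
                "density_per_um2": round(puncta_density(ps, r.mask), 6),
                "intensity_per_area": round(
                    intensity_per_area(img, ps, r.mask), 6),
                "mean_intensity_per_punctum": round(
                    float(np.mean([p.mean_intensity for p in ps.puncta])), 6)
                    if ps.puncta else 0.0,
            })
        if config.scheme is not None and len(config.channels) >= 2:
            ch_b = next((c for c in config.channels if c.lower() == "bassoon"),
                        config.channels[0])
            other = [c for c in config.channels if c != ch_b]
            ch_p = other[0]
            graph = associate_puncta(r.puncta[ch_b], r.puncta[ch_p],
                                     config.association_radius_nm)
            if config.scheme == "piccolo_bassoon":
                table = categorize_piccolo_bassoon(graph)
                hits = detect_sandwich(r.puncta[ch_p], r.puncta[ch_b], graph,
                                       config.sandwich_min_sep_nm,
                                       config.sandwich_max_sep_nm,
                                       config.sandwich_min_angle_deg)
                for h in hits:
                    sandwich_rows.append({
                        "group": r.group, "animal": r.animal,
                        "synapse": r.synapse,
                        "bassoon_label": h.bassoon_id,
                        "piccolo_label_1": h.piccolo_ids[0],
                        "piccolo_label_2": h.piccolo_ids[1],
                        "separation_nm": round(h.flank_separation_nm, 3),
                        "angle_deg": round(h.flank_angle_deg, 3),
                    })
            else:
                table = categorize_bassoon_vgcc(graph)
            if table.total > 0:
                table = normalize_category_counts(table)
            for cat, n in table.counts.items():
                category_rows.append({
                    "group": r.group, "animal": r.animal, "synapse": r.synapse,
                    "scheme": table.scheme, "category": cat, "count": n,
                    "normalized": round(table.normalized.get(cat, 0.0), 6),
                })

    puncta_df = pd.DataFrame(puncta_rows)
    synapse_df = pd.DataFrame(synapse_rows)
    category_df = pd.DataFrame(category_rows)
    sandwich_df = pd.DataFrame(
        sandwich_rows,
        columns=["group", "animal", "synapse", "bassoon_label",
                 "piccolo_label_1", "piccolo_label_2", "separation_nm",
                 "angle_deg"])
    stats_df = _group_comparisons(config, puncta_df, synapse_df)

    manifest = {
        "config": _config_to_jsonable(config),
        "n_synapses": len(results),
        "group_names": group_names,
    }
    bundle = ReportBundle(puncta=puncta_df, synapses=synapse_df,
                          categories=category_df, sandwich_hits=sandwich_df,
                          group_stats=stats_df, manifest=manifest,
                          results=results)
    if out_dir is not None:
        write_report(bundle, out_dir)
    log.info("pipeline complete: %d synapses in %.1fs", len(results),
             time.perf_counter() - t_start)
    return bundle


def _group_comparisons(config: PipelineConfig, puncta_df: pd.DataFrame,
                       synapse_df: pd.DataFrame) -> pd.DataFrame:
    """Mean ± SEM (or SD for FWHM) per group, and a two-tailed unpaired
    pooled t-test between the first two groups, per channel and measure.

    Per-synapse measures: puncta density and intensity per area.
    Per-punctum measures: mean intensity (all puncta) and FWHM (the
    hierarchically sampled puncta), pooled across synapses of a group.
    """
    if synapse_df.empty:
        return pd.DataFrame()
    groups = sorted(synapse_df["group"].unique())
    rows = []
    for ch in config.channels:
        measures: dict[str, dict[str, np.ndarray]] = {}
        for g in groups:
            sdf = synapse_df[(synapse_df.group == g) & (synapse_df.channel == ch)]
            pdf = puncta_df[(puncta_df.group == g) & (puncta_df.channel == ch)]
            fw = pdf[pdf.sampled & pdf.fwhm_nm.notna()]["fwhm_nm"]
            measures.setdefault("density_per_um2", {})[g] = sdf[
                "density_per_um2"].to_numpy()
            measures.setdefault("intensity_per_area", {})[g] = sdf[
                "intensity_per_area"].to_numpy()
            measures.setdefault("intensity_per_punctum", {})[g] = pdf[
                "mean_intensity"].to_numpy()
            measures.setdefault("fwhm_nm", {})[g] = fw.to_numpy()
        for measure, per_group in measures.items():
            row: dict = {"channel": ch, "measure": measure}
            for g in groups:
                v = per_group[g]
                if v.size >= 2:
                    s = summarize_group(v)
                    row[f"{g}_n"] = s.n
                    row[f"{g}_mean"] = round(s.mean, 6)
                    row[f"{g}_sd"] = round(s.sd, 6)
                    row[f"{g}_sem"] = round(s.sem, 6)
                else:
                    row[f"{g}_n"] = int(v.size)
            if len(groups) >= 2:
                a = per_group[groups[0]]
                b = per_group[groups[1]]
                if a.size >= 2 and b.size >= 2 and (a.var() > 0 or b.var() > 0):
                    t = unpaired_ttest(a, b)
                    row["t_statistic"] = round(t.t_statistic, 6)
                    row["df"] = t.degrees_of_freedom
                    row["p_value"] = float(f"{t.p_value:.6g}")
            rows.append(row)
    return pd.DataFrame(rows)


def _config_to_jsonable(config: PipelineConfig) -> dict:
    def conv(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: conv(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (tuple, list)):
            return [conv(x) for x in obj]
        if isinstance(obj, dict):
            return {k: conv(v) for k, v in obj.items()}
        return obj

    return conv(config)


def write_report(bundle: ReportBundle, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.puncta.to_csv(out / "puncta.csv", index=False)
    bundle.synapses.to_csv(out / "synapse_summary.csv", index=False)
    bundle.categories.to_csv(out / "coloc_categories.csv", index=False)
    bundle.sandwich_hits.to_csv(out / "sandwich_hits.csv", index=False)
    bundle.group_stats.to_csv(out / "group_stats.csv", index=False)
    (out / "manifest.json").write_text(
        json.dumps(bundle.manifest, indent=1, sort_keys=True))
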