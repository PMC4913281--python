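"""Synthetic dual-color STED scene generation with known ground truth.

The simulator emulates the acquisition geometry of dual-color STED imaging
of neuromuscular-junction active zones: diffraction-shaped puncta rendered
as isotropic 2D Gaussians (FWHM ~100-130 nm) on a 20 nm pixel grid, laid
out in the motifs seen at adult NMJs — two flanking puncta ~100 nm apart
sandwiching a punctum of the partner protein, tandem repeats of that
sandwich, fully colocalized pairs, and solitary puncta — inside a binary
synapse mask, with Poisson shot noise and Gaussian read noise.

Every generated punctum carries its ground-truth position, width, amplitude
and motif membership so that downstream segmentation, FWHM estimation and
colocalization categorization can be scored against truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import (
    FWHM_PER_SIGMA,
    ImageChannel,
    MaskError,
    PlacementError,
    SynapseMask,
)

MOTIF_TYPES = ("sandwich", "tandem_sandwich", "coloc_pair", "solitary")
MOTIF_ROLES = ("flank", "center", "solo", "pair_member")

# Per-channel punctum FWHM distributions (mean, SD in nm) matching the
# measured adult-NMJ values for the three active-zone proteins.
DEFAULT_FWHM_NM = {
    "vgcc": (103.4, 8.5),
    "bassoon": (126.4, 11.8),
    "piccolo": (107.6, 9.7),
}
FALLBACK_FWHM_NM = (110.0, 10.0)


@dataclass
class GroundTruthPunctum:
    punctum_id: int
    channel: str
    x_nm: float
    y_nm: float
    amplitude: float
    fwhm_true_nm: float
    motif_id: int | None = None
    motif_role: str = "solo"

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if self.fwhm_true_nm <= 0:
            raise ValueError("fwhm_true_nm must be positive")
        if self.motif_role not in MOTIF_ROLES:
            raise ValueError(f"unknown motif_role {self.motif_role!r}")
        if self.motif_role == "center" and self.motif_id is None:
            raise ValueError("center punctum requires a motif_id")


@dataclass
class MaskSpec:
    """Geometry of the synapse mask, in nm.

    shape "rectangle": params center_x_nm, center_y_nm, width_nm, height_nm.
    shape "ellipse_band": params center_x_nm, center_y_nm, outer_a_nm,
        outer_b_nm, band_fraction (band between band_fraction and 1 of the
        normalized elliptical radius; band_fraction 0 gives a full ellipse).
    shape "custom": params pixels (nested list of 0/1, realized as-is).

    fold_line_spacing_nm, when set, restricts the region to periodic stripes
    (junctional-fold lines) of width 60% of the spacing, running along y.
    """

    shape: str
    params: dict = field(default_factory=dict)
    fold_line_spacing_nm: float | None = None

    def __post_init__(self) -> None:
        if self.shape not in ("rectangle", "ellipse_band", "custom"):
            raise MaskError(f"unknown mask shape {self.shape!r}")
        if self.fold_line_spacing_nm is not None and self.fold_line_spacing_nm <= 0:
            raise MaskError("fold_line_spacing_nm must be positive")


@dataclass
class SceneSpec:
    """Complete description of one synthetic scene, including ground truth."""

    width_px: int
    height_px: int
    pixel_size_nm: float
    channels: list[str]
    puncta: list[GroundTruthPunctum]
    mask_spec: MaskSpec
    background_level: float = 5.0
    read_noise_sd: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("image dimensions must be positive")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel labels must be unique")
        if self.background_level < 0 or self.read_noise_sd < 0:
            raise ValueError("background and read noise must be nonnegative")
        w_nm = self.width_px * self.pixel_size_nm
        h_nm = self.height_px * self.pixel_size_nm
        for p in self.puncta:
            if p.channel not in self.channels:
                raise ValueError(f"punctum channel {p.channel!r} not in scene channels")
            if not (0 <= p.x_nm < w_nm and 0 <= p.y_nm < h_nm):
                raise ValueError(f"punctum {p.punctum_id} lies outside the image")

    def puncta_in_channel(self, channel: str) -> list[GroundTruthPunctum]:
        return [p for p in self.puncta if p.channel == channel]


@dataclass
class MotifSpec:
    """Request for a number of motifs of one type.

    For "sandwich"/"tandem_sandwich", flank puncta go to ``flank_channel``
    and center puncta to ``center_channel``.  For "coloc_pair" one punctum
    is placed in each of ``channels`` at the same location (plus jitter).
    For "solitary" a single punctum is placed in ``channels[0]``.
    """

    motif_type: str
    count: int
    channels: tuple[str, ...] = ("piccolo", "bassoon")
    flank_separation_nm: float = 100.0
    jitter_sd_nm: float = 5.0

    def __post_init__(self) -> None:
        if self.motif_type not in MOTIF_TYPES:
            raise ValueError(f"unknown motif_type {self.motif_type!r}")
        if self.count < 0:
            raise ValueError("count must be nonnegative")
        if self.flank_separation_nm <= 0:
            raise ValueError("flank_separation_nm must be positive")
        if self.jitter_sd_nm < 0:
            raise ValueError("jitter_sd_nm must be nonnegative")

    @property
    def flank_channel(self) -> str:
        return self.channels[0]

    @property
    def center_channel(self) -> str:
        return self.channels[1] if len(self.channels) > 1 else self.channels[0]


@dataclass
class SceneConfig:
    """Parameters for :func:`build_scene`.

    ``fwhm_nm`` maps channel label to a (mean, sd) pair of the Gaussian
    punctum FWHM distribution; channels absent from the map fall back to
    the measured per-protein defaults, or (110, 10) for unknown labels.
    ``amplitude_range`` is a uniform range of peak amplitudes above
    background, in counts.
    """

    width_px: int = 256
    height_px: int = 256
    pixel_size_nm: float = 20.0
    channels: tuple[str, ...] = ("piccolo", "bassoon")
    motifs: tuple[MotifSpec, ...] = ()
    fwhm_nm: dict = field(default_factory=dict)
    amplitude_range: tuple[float, float] = (120.0, 250.0)
    background_level: float = 5.0
    read_noise_sd: float = 1.0
    mask_spec: MaskSpec | None = None
    min_motif_spacing_nm: float = 400.0
    edge_margin_nm: float = 150.0
    count_distribution: str = "fixed"  # "fixed" or "poisson" motif counts
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.count_distribution not in ("fixed", "poisson"):
            raise ValueError("count_distribution must be 'fixed' or 'poisson'")


def _fwhm_params(config: SceneConfig, channel: str) -> tuple[float, float]:
    if channel in config.fwhm_nm:
        mean, sd = config.fwhm_nm[channel]
    else:
        mean, sd = DEFAULT_FWHM_NM.get(channel, FALLBACK_FWHM_NM)
    return float(mean), float(sd)


def _sample_fwhm(rng: np.random.Generator, config: SceneConfig, channel: str) -> float:
    mean, sd = _fwhm_params(config, channel)
    # truncate far tails so widths stay physical
    return float(np.clip(rng.normal(mean, sd), max(40.0, mean - 3 * sd), mean + 3 * sd))


def _sample_amplitude(rng: np.random.Generator, config: SceneConfig) -> float:
    lo, hi = config.amplitude_range
    return float(rng.uniform(lo, hi))


def _default_mask_spec(config: SceneConfig) -> MaskSpec:
    w_nm = config.width_px * config.pixel_size_nm
    h_nm = config.height_px * config.pixel_size_nm
    return MaskSpec(
        shape="rectangle",
        params={
            "center_x_nm": w_nm / 2,
            "center_y_nm": h_nm / 2,
            "width_nm": 0.85 * w_nm,
            "height_nm": 0.85 * h_nm,
        },
    )


def realize_mask(spec: MaskSpec, width_px: int, height_px: int,
                 pixel_size_nm: float) -> SynapseMask:
    """Rasterize a mask geometry: a pixel belongs if its center is inside."""
    px = pixel_size_nm
    rows, cols = np.mgrid[0:height_px, 0:width_px]
    x = (cols + 0.5) * px
    y = (rows + 0.5) * px
    if spec.shape == "rectangle":
        p = spec.params
        inside = (
            (np.abs(x - p["center_x_nm"]) <= p["width_nm"] / 2)
            & (np.abs(y - p["center_y_nm"]) <= p["height_nm"] / 2)
        )
    elif spec.shape == "ellipse_band":
        p = spec.params
        r2 = ((x - p["center_x_nm"]) / p["outer_a_nm"]) ** 2 + (
            (y - p["center_y_nm"]) / p["outer_b_nm"]
        ) ** 2
        band = float(p.get("band_fraction", 0.0))
        inside = (r2 <= 1.0) & (r2 >= band**2)
    elif spec.shape == "custom":
        inside = np.asarray(spec.params["pixels"], dtype=bool)
        if inside.shape != (height_px, width_px):
            raise MaskError("custom mask shape does not match image dimensions")
    else:  # pragma: no cover - guarded in MaskSpec
        raise MaskError(f"unknown mask shape {spec.shape!r}")
    if spec.fold_line_spacing_nm is not None:
        s = spec.fold_line_spacing_nm
        inside = inside & ((x % s) < 0.6 * s)
    if not inside.any():
        raise MaskError("mask geometry yields an empty mask within the image")
    return SynapseMask(pixels=inside, pixel_size_nm=pixel_size_nm)


def _motif_puncta(rng: np.random.Generator, config: SceneConfig, spec: MotifSpec,
                  cx: float, cy: float, motif_id: int,
                  next_id: int) -> list[GroundTruthPunctum]:
    """Realize one motif instance centred at (cx, cy) with random orientation."""
    theta = rng.uniform(0.0, math.pi)
    ux, uy = math.cos(theta), math.sin(theta)
    jit = lambda: rng.normal(0.0, spec.jitter_sd_nm, size=2)  # noqa: E731
    sep = spec.flank_separation_nm
    # puncta within one active zone share a similar protein content: one
    # motif-level amplitude with 10% per-punctum scatter
    motif_amp = _sample_amplitude(rng, config)
    out: list[GroundTruthPunctum] = []

    def add(channel: str, dx: float, dy: float, role: str) -> None:
        jx, jy = jit()
        out.append(
            GroundTruthPunctum(
                punctum_id=next_id + len(out),
                channel=channel,
                x_nm=cx + dx + jx,
                y_nm=cy + dy + jy,
                amplitude=motif_amp * float(np.clip(rng.normal(1.0, 0.1), 0.6, 1.4)),
                fwhm_true_nm=_sample_fwhm(rng, config, channel),
                motif_id=motif_id,
                motif_role=role,
            )
        )

    if spec.motif_type == "sandwich":
        add(spec.flank_channel, -ux * sep / 2, -uy * sep / 2, "flank")
        add(spec.flank_channel, ux * sep / 2, uy * sep / 2, "flank")
        add(spec.center_channel, 0.0, 0.0, "center")
    elif spec.motif_type == "tandem_sandwich":
        for k in (-1.0, 0.0, 1.0):
            add(spec.flank_channel, ux * k * sep, uy * k * sep, "flank")
        for k in (-0.5, 0.5):
            add(spec.center_channel, ux * k * sep, uy * k * sep, "center")
    elif spec.motif_type == "coloc_pair":
        for channel in spec.channels[:2]:
            add(channel, 0.0, 0.0, "pair_member")
    elif spec.motif_type == "solitary":
        add(spec.channels[0], 0.0, 0.0, "solo")
    return out


def build_scene(config: SceneConfig) -> SceneSpec:
    """Place the requested motifs inside the mask and return the full scene.

    Motif centres are drawn uniformly inside the mask, rejecting draws
    closer than ``min_motif_spacing_nm`` to an already placed motif or
    closer than ``edge_margin_nm + motif radius`` to the image border.
    Deterministic for a given ``rng_seed``.
    """
    rng = np.random.default_rng(config.rng_seed)
    mask_spec = config.mask_spec or _default_mask_spec(config)
    mask = realize_mask(mask_spec, config.width_px, config.height_px,
                        config.pixel_size_nm)
    px = config.pixel_size_nm
    w_nm, h_nm = config.width_px * px, config.height_px * px
    # motif centres are drawn from the mask interior: at least
    # edge_margin_nm + motif reach from the mask boundary, so every ground
    # truth punctum lies safely inside the analysis region
    dist_to_edge = ndimage.distance_transform_edt(mask.pixels) * px

    centers: list[tuple[float, float]] = []
    puncta: list[GroundTruthPunctum] = []
    motif_id = 0
    for spec in config.motifs:
        reach = spec.flank_separation_nm if spec.motif_type == "tandem_sandwich" \
            else spec.flank_separation_nm / 2 if spec.motif_type == "sandwich" else 0.0
        margin = config.edge_margin_nm + reach
        interior = dist_to_edge > margin
        mask_rows, mask_cols = np.nonzero(interior)
        if mask_rows.size == 0:
            raise PlacementError(
                f"mask interior is empty at edge_margin_nm={config.edge_margin_nm} "
                f"plus motif reach {reach:.0f} nm"
            )
        n_motifs = (spec.count if config.count_distribution == "fixed"
                    else int(rng.poisson(spec.count)))
        for _ in range(n_motifs):
            for _attempt in range(2000):
                i = rng.integers(0, mask_rows.size)
                cx = (mask_cols[i] + rng.uniform()) * px
                cy = (mask_rows[i] + rng.uniform()) * px
                if not (margin <= cx < w_nm - margin and margin <= cy < h_nm - margin):
                    continue
                if all(
                    (cx - ox) ** 2 + (cy - oy) ** 2 >= config.min_motif_spacing_nm**2
                    for ox, oy in centers
                ):
                    break
            else:
                raise PlacementError(
                    f"could not place {spec.motif_type!r} motif {len(centers) + 1} "
                    f"inside the mask at min_motif_spacing_nm="
                    f"{config.min_motif_spacing_nm} with edge_margin_nm="
                    f"{config.edge_margin_nm}"
                )
            centers.append((cx, cy))
            puncta.extend(
                _motif_puncta(rng, config, spec, cx, cy, motif_id, len(puncta))
            )
            motif_id += 1

    return SceneSpec(
        width_px=config.width_px,
        height_px=config.height_px,
        pixel_size_nm=config.pixel_size_nm,
        channels=list(config.channels),
        puncta=puncta,
        mask_spec=mask_spec,
        background_level=config.background_level,
        read_noise_sd=config.read_noise_sd,
        rng_seed=config.rng_seed,
    )


def render_channel(scene: SceneSpec, channel: str) -> ImageChannel:
    """Render the noiseless image of one channel.

    Each punctum contributes an isotropic 2D Gaussian,
    ``amplitude * exp(-((x-x0)^2 + (y-y0)^2) / (2 sigma^2))`` with
    ``sigma = FWHM / (2 sqrt(2 ln 2))``, evaluated at pixel centres on top
    of the uniform background.
    """
    if channel not in scene.channels:
        raise ValueError(f"unknown channel {channel!r}")
    px = scene.pixel_size_nm
    img = np.full((scene.height_px, scene.width_px), float(scene.background_level))
    for p in scene.puncta_in_channel(channel):
        sigma = p.fwhm_true_nm / FWHM_PER_SIGMA
        half = int(math.ceil(5.0 * sigma / px)) + 1
        c0 = int(p.x_nm / px)
        r0 = int(p.y_nm / px)
        r_lo, r_hi = max(0, r0 - half), min(scene.height_px, r0 + half + 1)
        c_lo, c_hi = max(0, c0 - half), min(scene.width_px, c0 + half + 1)
        if r_lo >= r_hi or c_lo >= c_hi:
            continue
        xs = (np.arange(c_lo, c_hi) + 0.5) * px
        ys = (np.arange(r_lo, r_hi) + 0.5) * px
        gx = np.exp(-((xs - p.x_nm) ** 2) / (2 * sigma**2))
        gy = np.exp(-((ys - p.y_nm) ** 2) / (2 * sigma**2))
        img[r_lo:r_hi, c_lo:c_hi] += p.amplitude * np.outer(gy, gx)
    return ImageChannel(pixels=img, pixel_size_nm=px, channel=channel)


def apply_noise(image: ImageChannel, read_noise_sd: float, seed: int) -> ImageChannel:
    """Photon-counting noise: Poisson(pixel) + Normal(0, read_noise_sd), clipped at 0."""
    if np.any(image.pixels < 0):
        raise ValueError("input image must be nonnegative")
    if read_noise_sd < 0:
        raise ValueError("read_noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    noisy = rng.poisson(image.pixels).astype(float)
    if read_noise_sd > 0:
        noisy += rng.normal(0.0, read_noise_sd, size=noisy.shape)
    return image.copy_with(np.clip(noisy, 0.0, None))


def render_noisy_channel(scene: SceneSpec, channel: str,
                         seed: int | None = None) -> ImageChannel:
    """Convenience: render a channel and apply the scene's noise model.

    The noise seed defaults to a deterministic combination of the scene seed
    and the channel index, so the two channels of one scene receive
    independent noise.
    """
    clean = render_channel(scene, channel)
    if seed is None:
        seed = int(
            np.random.SeedSequence(
                [scene.rng_seed, scene.channels.index(channel)]
            ).generate_state(1)[0]
        )
    return apply_noise(clean, scene.read_noise_sd, seed)


# ---------------------------------------------------------------------------
# Ground-truth I/O

GT_COLUMNS = ["punctum_id", "channel", "x_nm", "y_nm", "amplitude",
              "fwhm_true_nm", "motif_id", "motif_role"]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".scene.json")


def write_ground_truth(scene: SceneSpec, path: str | Path) -> None:
    """Write the puncta table as CSV plus a JSON sidecar with scene metadata."""
    path = Path(path)
    rows = [
        {
            "punctum_id": p.punctum_id,
            "channel": p.channel,
            "x_nm": round(p.x_nm, 6),
            "y_nm": round(p.y_nm, 6),
            "amplitude": round(p.amplitude, 6),
            "fwhm_true_nm": round(p.fwhm_true_nm, 6),
            "motif_id": "" if p.motif_id is None else p.motif_id,
            "motif_role": p.motif_role,
        }
        for p in scene.puncta
    ]
    pd.DataFrame(rows, columns=GT_COLUMNS).to_csv(path, index=False)
    if scene.mask_spec.shape == "custom":
        raise ValueError("custom masks cannot be serialized to a scene sidecar")
    meta = {
        "width_px": scene.width_px,
        "height_px": scene.height_px,
        "pixel_size_nm": scene.pixel_size_nm,
        "channels": scene.channels,
        "background_level": scene.background_level,
        "read_noise_sd": scene.read_noise_sd,
        "rng_seed": scene.rng_seed,
        "mask_spec": {
            "shape": scene.mask_spec.shape,
            "params": scene.mask_spec.params,
            "fold_line_spacing_nm": scene.mask_spec.fold_line_spacing_nm,
        },
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_ground_truth(path: str | Path) -> SceneSpec:
    """Inverse of :func:`write_ground_truth` (coordinates round-trip to 1e-3 nm)."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in GT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"ground-truth CSV is missing columns: {missing}")
    if (df["fwhm_true_nm"] <= 0).any():
        raise ValueError("fwhm_true_nm must be positive in ground-truth CSV")
    if (df["amplitude"] <= 0).any():
        raise ValueError("amplitude must be positive in ground-truth CSV")
    meta = json.loads(_sidecar_path(path).read_text())
    puncta = [
        GroundTruthPunctum(
            punctum_id=int(r.punctum_id),
            channel=str(r.channel),
            x_nm=float(r.x_nm),
            y_nm=float(r.y_nm),
            amplitude=float(r.amplitude),
            fwhm_true_nm=float(r.fwhm_true_nm),
            motif_id=None if pd.isna(r.motif_id) else int(r.motif_id),
            motif_role=str(r.motif_role),
        )
        for r in df.itertuples()
    ]
    ms = meta["mask_spec"]
    return SceneSpec(
        width_px=int(meta["width_px"]),
        height_px=int(meta["height_px"]),
        pixel_size_nm=float(meta["pixel_size_nm"]),
        channels=list(meta["channels"]),
        puncta=puncta,
        mask_spec=MaskSpec(shape=ms["shape"], params=ms["params"],
                           fold_line_spacing_nm=ms["fold_line_spacing_nm"]),
        background_level=float(meta["background_level"]),
        read_noise_sd=float(meta["read_noise_sd"]),
        rng_seed=int(meta["rng_seed"]),
    )
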