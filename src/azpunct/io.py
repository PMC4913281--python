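"""Reading and writing images, masks, and puncta tables.

Images and masks travel as single-plane 16-bit unsigned TIFF with a JSON
sidecar (``<name>.meta.json``) carrying the physical pixel size and the
channel label; puncta go to/from CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .core import ImageChannel, PunctaSet, PunctumRecord, SynapseMask

PUNCTA_COLUMNS = ["label", "centroid_x_nm", "centroid_y_nm", "area_px",
                  "area_um2", "peak_intensity", "mean_intensity",
                  "integrated_intensity", "fwhm_nm", "border_flag"]


def _meta_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_image(image: ImageChannel, path: str | Path) -> None:
    path = Path(path)
    data = np.clip(np.round(image.pixels), 0, np.iinfo(np.uint16).max)
    tifffile.imwrite(path, data.astype(np.uint16))
    _meta_path(path).write_text(json.dumps(
        {"pixel_size_nm": image.pixel_size_nm, "channel": image.channel}))


def read_image(path: str | Path, pixel_size_nm: float | None = None,
               channel: str | None = None) -> ImageChannel:
    """Read an image; sidecar metadata is used unless overridden."""
    path = Path(path)
    pixels = tifffile.imread(path).astype(float)
    meta = {}
    if _meta_path(path).exists():
        meta = json.loads(_meta_path(path).read_text())
    px = pixel_size_nm if pixel_size_nm is not None else meta.get("pixel_size_nm")
    if px is None:
        raise ValueError(f"no pixel size for {path}: pass pixel_size_nm or "
                         "provide a sidecar")
    ch = channel if channel is not None else meta.get("channel", path.stem)
    return ImageChannel(pixels=pixels, pixel_size_nm=float(px), channel=str(ch))


def write_mask(mask: SynapseMask, path: str | Path) -> None:
    path = Path(path)
    tifffile.imwrite(path, mask.pixels.astype(np.uint16) * np.uint16(65535))
    _meta_path(path).write_text(json.dumps({"pixel_size_nm": mask.pixel_size_nm}))


def read_mask(path: str | Path, pixel_size_nm: float | None = None) -> SynapseMask:
    path = Path(path)
    pixels = tifffile.imread(path) > 0
    meta = {}
    if _meta_path(path).exists():
        meta = json.loads(_meta_path(path).read_text())
    px = pixel_size_nm if pixel_size_nm is not None else meta.get("pixel_size_nm")
    if px is None:
        raise ValueError(f"no pixel size for {path}")
    return SynapseMask(pixels=pixels, pixel_size_nm=float(px))


def write_label_image(puncta: PunctaSet, path: str | Path) -> None:
    if puncta.label_image is None:
        raise ValueError("puncta set has no label image")
    tifffile.imwrite(Path(path), puncta.label_image.astype(np.uint16))


def puncta_to_frame(puncta: PunctaSet) -> pd.DataFrame:
    rows = [{
        "label": p.label,
        "centroid_x_nm": p.centroid_x_nm,
        "centroid_y_nm": p.centroid_y_nm,
        "area_px": p.area_px,
        "area_um2": p.area_um2,
        "peak_intensity": p.peak_intensity,
        "mean_intensity": p.mean_intensity,
        "integrated_intensity": p.integrated_intensity,
        "fwhm_nm": p.fwhm_nm,
        "border_flag": p.border_flag,
    } for p in puncta.puncta]
    return pd.DataFrame(rows, columns=PUNCTA_COLUMNS)


def write_puncta_csv(puncta: PunctaSet, path: str | Path) -> None:
    puncta_to_frame(puncta).to_csv(Path(path), index=False)


def read_puncta_csv(path: str | Path, channel: str,
                    pixel_size_nm: float) -> PunctaSet:
    """Load a puncta table written by :func:`write_puncta_csv`.

    The returned set has no label image, so only centroid-distance
    association is possible downstream.
    """
    df = pd.read_csv(Path(path))
    missing = [c for c in PUNCTA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"puncta CSV is missing columns: {missing}")
    records = [
        PunctumRecord(
            label=int(r.label),
            centroid_x_nm=float(r.centroid_x_nm),
            centroid_y_nm=float(r.centroid_y_nm),
            area_px=int(r.area_px),
            area_um2=float(r.area_um2),
            peak_intensity=float(r.peak_intensity),
            mean_intensity=float(r.mean_intensity),
            integrated_intensity=float(r.integrated_intensity),
            fwhm_nm=None if pd.isna(r.fwhm_nm) else float(r.fwhm_nm),
            border_flag=bool(r.border_flag),
        )
        for r in df.itertuples()
    ]
    return PunctaSet(puncta=records, label_image=None, channel=channel,
                     pixel_size_nm=pixel_size_nm)
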