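"""Shared container types for the puncta-quantification pipeline.

Coordinate convention used throughout the package: continuous physical
coordinates in nanometres, origin at the top-left image corner, x along
columns and y along rows.  The centre of pixel (row r, column c) sits at
``((c + 0.5) * pixel_size_nm, (r + 0.5) * pixel_size_nm)`` with 0-based
indices, so sub-pixel placement is unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Conversion factor between the full width at half maximum of a Gaussian
#: and its standard deviation: FWHM = sigma * 2*sqrt(2*ln 2).
FWHM_PER_SIGMA: float = 2.0 * float(np.sqrt(2.0 * np.log(2.0)))


class AzpunctError(Exception):
    """Base class for errors raised by this package."""


class MaskError(AzpunctError):
    """Synapse mask is empty, malformed, or incompatible with the image."""


class PlacementError(AzpunctError):
    """Requested motifs cannot be placed inside the mask at the minimum spacing."""


class NoObjectPeakError(AzpunctError):
    """Histogram has no local maximum brighter than the background peak."""


class ProfileBoundsError(AzpunctError):
    """A line profile would leave the image bounds."""


class NoCrossingError(AzpunctError):
    """A profile never falls to half maximum on one side of its peak."""


class ConfigError(AzpunctError):
    """A pipeline or scene configuration is incomplete or inconsistent."""


@dataclass
class ImageChannel:
    """A single-channel, single-plane intensity image with physical pixel size."""

    pixels: np.ndarray
    pixel_size_nm: float
    channel: str

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2D array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels must be finite")
        if np.any(self.pixels < 0):
            raise ValueError("pixels must be nonnegative")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def copy_with(self, pixels: np.ndarray) -> "ImageChannel":
        return ImageChannel(pixels=pixels, pixel_size_nm=self.pixel_size_nm,
                            channel=self.channel)


@dataclass
class SynapseMask:
    """Binary analysis region (the AChR-cluster footprint) on the image grid."""

    pixels: np.ndarray
    pixel_size_nm: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise MaskError("mask must be a non-empty 2D array")
        if self.pixel_size_nm <= 0:
            raise MaskError("pixel_size_nm must be positive")
        if not self.pixels.any():
            raise MaskError("mask is empty (no true pixels)")

    @property
    def area_um2(self) -> float:
        """Mask area in µm²: true-pixel count × (pixel_size_nm / 1000)²."""
        return float(self.pixels.sum()) * (self.pixel_size_nm / 1000.0) ** 2


@dataclass
class PunctumRecord:
    """Measurements of one segmented punctum."""

    label: int
    centroid_x_nm: float
    centroid_y_nm: float
    area_px: int
    area_um2: float
    peak_intensity: float
    mean_intensity: float
    integrated_intensity: float
    fwhm_nm: float | None = None
    border_flag: bool = False


@dataclass
class PunctaSet:
    """Segmentation output for one channel: records plus the label image.

    ``label_image`` may be None for sets loaded from a table (centroid
    geometry only); pixel-overlap queries are then unavailable.
    """

    puncta: list[PunctumRecord]
    label_image: np.ndarray | None
    channel: str
    pixel_size_nm: float

    def __post_init__(self) -> None:
        labels = {p.label for p in self.puncta}
        if len(labels) != len(self.puncta):
            raise ValueError("punctum labels must be unique")
        if self.label_image is not None:
            present = set(np.unique(self.label_image)) - {0}
            if labels != present:
                raise ValueError("records do not match label image")

    def __len__(self) -> int:
        return len(self.puncta)

    def by_label(self, label: int) -> PunctumRecord:
        for p in self.puncta:
            if p.label == label:
                return p
        raise KeyError(f"no punctum with label {label}")
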