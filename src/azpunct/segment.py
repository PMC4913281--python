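"""Auto-thresholding, punctum segmentation, and iterative deconvolution.

The threshold follows the classic "auto threshold for light objects"
gray-value histogram rule: the background is the histogram's largest peak,
the objects form a peak on its bright side, and the threshold sits at the
trough between the two.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

from .core import (
    FWHM_PER_SIGMA,
    ImageChannel,
    MaskError,
    NoObjectPeakError,
    PunctaSet,
    PunctumRecord,
    SynapseMask,
)

DEFAULT_N_BINS = 256
DEFAULT_MIN_SIZE_PX = 4


@dataclass
class ThresholdResult:
    threshold: float
    histogram: np.ndarray
    bin_edges: np.ndarray
    background_peak_bin: int
    object_peak_bin: int
    trough_bin: int


def _local_maxima(counts: np.ndarray) -> list[int]:
    """Indices of strict local maxima; a plateau flanked by strictly lower
    counts is a maximum at its dimmest bin.  Endpoints see a virtual
    zero-count neighbour beyond the histogram."""
    ext = np.concatenate(([-1.0], counts.astype(float), [-1.0]))
    maxima: list[int] = []
    i = 1
    while i <= len(counts):
        j = i
        while j + 1 <= len(counts) and ext[j + 1] == ext[i]:
            j += 1
        if ext[i - 1] < ext[i] and ext[j + 1] < ext[i]:
            maxima.append(i - 1)  # dimmest bin of the plateau
        i = j + 1
    return maxima


def trough_threshold(counts: np.ndarray, bin_edges: np.ndarray) -> ThresholdResult:
    """Locate background peak, object peak, and the trough between them.

    background peak: the modal bin (ties -> dimmest).  object peak: among
    local maxima strictly brighter than the background peak, the one with
    the highest count (ties -> dimmest).  trough: the minimum-count bin
    strictly between the two peaks (ties -> dimmest); when the peaks are
    adjacent the trough coincides with the object peak bin.  The threshold
    is the trough bin's upper gray edge (its lower edge in the adjacent
    case); pixels strictly above it are objects.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 1 or counts.size < 2:
        raise ValueError("histogram must have at least two bins")
    background = int(np.argmax(counts))
    maxima = [m for m in _local_maxima(counts) if m > background]
    if not maxima:
        raise NoObjectPeakError(
            "histogram has no local maximum brighter than the background peak"
        )
    # highest count, ties toward the dimmest bin
    best_count = max(counts[m] for m in maxima)
    best = min(m for m in maxima if counts[m] == best_count)
    between = np.arange(background + 1, best)
    if between.size:
        trough = int(between[np.argmin(counts[between])])
        threshold = float(bin_edges[trough + 1])
    else:
        trough = best
        threshold = float(bin_edges[trough])
    return ThresholdResult(
        threshold=threshold,
        histogram=counts,
        bin_edges=np.asarray(bin_edges, dtype=float),
        background_peak_bin=background,
        object_peak_bin=best,
        trough_bin=trough,
    )


def auto_threshold_light(image: ImageChannel, mask: SynapseMask,
                         n_bins: int = DEFAULT_N_BINS,
                         smooth_bins: int = 3) -> ThresholdResult:
    """Histogram-trough threshold of the masked pixels of one channel.

    Binning spans [min, max] of the masked pixels with ``n_bins`` equal
    bins; integer-valued images whose masked gray range does not exceed
    ``n_bins`` are binned per gray level instead.  The histogram is
    smoothed with a ``smooth_bins``-wide moving average (1 disables) before
    the peaks and trough are located, so single-bin sampling fluctuations
    on the flank of the background peak are not mistaken for the object
    peak; on sparse images that mistake collapses the threshold into the
    background.
    """
    if image.pixels.shape != mask.pixels.shape:
        raise MaskError("image and mask shapes differ")
    if smooth_bins < 1 or smooth_bins % 2 == 0:
        raise ValueError("smooth_bins must be a positive odd integer")
    values = image.pixels[mask.pixels]
    if values.size < 100:
        raise MaskError(f"mask covers only {values.size} pixels (need >= 100)")
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        raise NoObjectPeakError("masked image is constant")
    integral = np.allclose(values, np.round(values))
    if integral and (hi - lo) <= n_bins:
        edges = np.arange(np.floor(lo) - 0.5, np.floor(hi) + 1.5)
    else:
        edges = np.linspace(lo, hi, n_bins + 1)
    counts, edges = np.histogram(values, bins=edges)
    counts = counts.astype(float)
    if smooth_bins > 1:
        counts = ndimage.uniform_filter1d(counts, smooth_bins, mode="constant")
    return trough_threshold(counts, edges)


DEFAULT_SPLIT_MIN_DISTANCE_PX = 2
DEFAULT_SPLIT_REL_HEIGHT = 0.25


def _split_labels(pixels: np.ndarray, binary: np.ndarray, labels: np.ndarray,
                  min_distance_px: int, rel_height: float) -> np.ndarray:
    """Marker-controlled watershed split of multi-peaked components.

    Markers are intensity local maxima at least ``min_distance_px`` apart
    within each component, kept when they reach ``rel_height`` times the
    component's own maximum (so dim shoulders and noise spikes do not
    oversplit).  Components with a single surviving marker are unchanged.
    """
    peaks = peak_local_max(pixels, min_distance=min_distance_px, labels=labels,
                           exclude_border=False)
    if peaks.shape[0] == 0:
        return labels
    comp_max = ndimage.maximum(pixels, labels=labels,
                               index=np.arange(1, labels.max() + 1))
    comp_max = np.concatenate([[np.inf], np.atleast_1d(comp_max)])
    keep = []
    for r, c in peaks:
        lab = labels[r, c]
        if pixels[r, c] >= rel_height * comp_max[lab]:
            keep.append((r, c))
    markers = np.zeros_like(labels)
    for i, (r, c) in enumerate(keep, start=1):
        markers[r, c] = i
    return watershed(-pixels, markers=markers, mask=binary, connectivity=2)


def segment_puncta(image: ImageChannel, threshold: float, mask: SynapseMask,
                   min_size_px: int = DEFAULT_MIN_SIZE_PX,
                   split_touching: bool = False,
                   split_min_distance_px: int = DEFAULT_SPLIT_MIN_DISTANCE_PX,
                   split_rel_height: float = DEFAULT_SPLIT_REL_HEIGHT) -> PunctaSet:
    """Label thresholded objects and keep puncta belonging to the synapse.

    Objects are 8-connected components of pixels strictly above the
    threshold.  A component is kept when its intensity-weighted centroid
    falls inside the mask and its pixel count is at least ``min_size_px``.
    Components touching the image border are flagged.

    With ``split_touching`` enabled, components containing two or more
    comparable intensity maxima (e.g. flanking puncta ~100 nm apart that a
    global threshold cannot separate) are divided between their peaks by a
    marker-controlled watershed before measurement.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    if min_size_px < 1:
        raise ValueError("min_size_px must be >= 1")
    if image.pixels.shape != mask.pixels.shape:
        raise MaskError("image and mask shapes differ")
    binary = image.pixels > threshold
    labels = measure.label(binary, connectivity=2)
    if split_touching and labels.max() > 0:
        labels = _split_labels(image.pixels, binary, labels,
                               split_min_distance_px, split_rel_height)
    px = image.pixel_size_nm
    h, w = image.pixels.shape
    out_labels = np.zeros_like(labels)
    records: list[PunctumRecord] = []
    next_label = 1
    for region in measure.regionprops(labels, intensity_image=image.pixels):
        if region.area < min_size_px:
            continue
        ry, rx = region.centroid_weighted
        r_idx = min(h - 1, max(0, int(round(ry - 0.0))))
        c_idx = min(w - 1, max(0, int(round(rx - 0.0))))
        if not mask.pixels[r_idx, c_idx]:
            continue
        min_r, min_c, max_r, max_c = region.bbox
        border = min_r == 0 or min_c == 0 or max_r == h or max_c == w
        values = region.image_intensity[region.image]
        records.append(
            PunctumRecord(
                label=next_label,
                centroid_x_nm=(rx + 0.5) * px,
                centroid_y_nm=(ry + 0.5) * px,
                area_px=int(region.area),
                area_um2=float(region.area) * (px / 1000.0) ** 2,
                peak_intensity=float(values.max()),
                mean_intensity=float(values.mean()),
                integrated_intensity=float(values.sum()),
                border_flag=bool(border),
            )
        )
        out_labels[labels == region.label] = next_label
        next_label += 1
    return PunctaSet(puncta=records, label_image=out_labels,
                     channel=image.channel, pixel_size_nm=px)


def deconvolve(image: ImageChannel, psf_fwhm_nm: float,
               iterations: int) -> ImageChannel:
    """Richardson–Lucy deconvolution with an isotropic Gaussian PSF.

    Multiplicative expectation-maximization updates with reflective
    boundaries, so the result is nonnegative and total flux is conserved.
    ``iterations = 0`` returns the input unchanged.
    """
    if psf_fwhm_nm <= 0:
        raise ValueError("psf_fwhm_nm must be positive")
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    if iterations == 0:
        return image.copy_with(image.pixels.copy())
    sigma_px = psf_fwhm_nm / FWHM_PER_SIGMA / image.pixel_size_nm
    data = image.pixels
    tiny = 1e-12
    est = np.clip(data, tiny, None).astype(float)
    for _ in range(iterations):
        blurred = ndimage.gaussian_filter(est, sigma_px, mode="reflect")
        ratio = data / np.clip(blurred, tiny, None)
        est = est * ndimage.gaussian_filter(ratio, sigma_px, mode="reflect")
    return image.copy_with(np.clip(est, 0.0, None))
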