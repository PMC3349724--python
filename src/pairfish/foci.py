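"""Per-nucleus FISH focus detection.

Each segmented nucleus is analysed independently: a crop of the smoothed
FISH channel is taken over the nucleus pixel set, thresholded at

    median(intensities) + k_sd * SD(intensities)      (k_sd = 2 by default)

and the connected components of above-threshold pixels are kept as foci
after a size filter.  The SD is the sample standard deviation of the
intensities within the nucleus, computed on the smoothed (not
background-subtracted) channel.  Touching foci are deliberately not
re-split: a merged signal reads out as a single focus, i.e. paired.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import gaussian

from .errors import AlignmentError, DegenerateNucleusError
from .image import Channel, ImagePlane
from .segment import NucleusRecord


@dataclass
class FociParams:
    """Focus-detection tuning knobs.

    k_sd
        Multiplier on the within-nucleus intensity SD added to the median.
    min_focus_area_px / max_focus_area_fraction
        Size filter: components outside
        [min_focus_area_px, max_focus_area_fraction * nucleus area] are
        rejected (guards against single noise pixels and against a whole
        nucleus lighting up).
    strict_inequality
        Pixels must exceed the threshold strictly; keeps zero-variance
        regions focus-free.
    smooth_sigma_px
        Gaussian smoothing applied to the FISH plane before thresholding.
    """

    k_sd: float = 2.0
    min_focus_area_px: int = 2
    max_focus_area_fraction: float = 0.25
    strict_inequality: bool = True
    smooth_sigma_px: float = 1.0

    def __post_init__(self) -> None:
        if self.k_sd < 0:
            raise ValueError("k_sd must be non-negative")
        if not 0 < self.max_focus_area_fraction <= 1:
            raise ValueError("max_focus_area_fraction must be in (0, 1]")
        if self.min_focus_area_px < 1:
            raise ValueError("min_focus_area_px must be >= 1")


@dataclass
class FocusRecord:
    """One detected FISH spot inside one nucleus.

    ``centroid_um`` is the intensity-weighted centroid (x, y) in
    micrometres; ``pixels`` is an (n, 2) array of (row, col) indices, a
    subset of the nucleus pixel set.
    """

    channel: Channel
    nucleus_label: int
    pixels: np.ndarray
    area_px: int
    centroid_um: tuple[float, float]
    peak_intensity: float

    def pixel_set(self) -> set[tuple[int, int]]:
        return {(int(r), int(c)) for r, c in self.pixels}


def smooth_channel(img: ImagePlane, p: FociParams | None = None) -> ImagePlane:
    """Gaussian-smooth a FISH plane prior to per-nucleus thresholding."""
    p = p or FociParams()
    sm = gaussian(img.raster.astype(np.float64), sigma=p.smooth_sigma_px,
                  preserve_range=True)
    return ImagePlane(sm, img.channel, img.pixel_size_um)


def nucleus_threshold(
    channel_img: ImagePlane, nucleus: NucleusRecord, p: FociParams | None = None
) -> float:
    """median + k_sd * sample-SD of the intensities inside one nucleus."""
    p = p or FociParams()
    if nucleus.pixel_count < 2:
        raise DegenerateNucleusError(
            f"nucleus {nucleus.label} has {nucleus.pixel_count} pixel(s)")
    vals = channel_img.raster[nucleus.rows, nucleus.cols].astype(np.float64)
    return float(np.median(vals) + p.k_sd * np.std(vals, ddof=1))


def detect_foci(
    channel_img: ImagePlane, nucleus: NucleusRecord, p: FociParams | None = None
) -> list[FocusRecord]:
    """Detect FISH foci within one nucleus of an aligned channel plane.

    Returns records sorted by (row, col) of their first pixel, so output
    order is deterministic.
    """
    p = p or FociParams()
    raster = channel_img.raster
    thresh = nucleus_threshold(channel_img, nucleus, p)

    r0, r1 = nucleus.rows.min(), nucleus.rows.max() + 1
    c0, c1 = nucleus.cols.min(), nucleus.cols.max() + 1
    if r1 > raster.shape[0] or c1 > raster.shape[1]:
        raise AlignmentError("channel raster smaller than the nucleus frame")
    crop = raster[r0:r1, c0:c1].astype(np.float64)
    inside = np.zeros(crop.shape, dtype=bool)
    inside[nucleus.rows - r0, nucleus.cols - c0] = True

    above = (crop > thresh) if p.strict_inequality else (crop >= thresh)
    candidate = above & inside
    if not candidate.any():
        return []

    labels, n = ndi.label(candidate, structure=np.ones((3, 3), dtype=bool))
    max_area = p.max_focus_area_fraction * nucleus.pixel_count
    px = channel_img.pixel_size_um
    out: list[FocusRecord] = []
    for lab in range(1, n + 1):
        rows, cols = np.nonzero(labels == lab)
        area = rows.size
        if area < p.min_focus_area_px or area > max_area:
            continue
        weights = crop[rows, cols]
        wsum = weights.sum()
        cx = float(((cols + c0) * weights).sum() / wsum * px)
        cy = float(((rows + r0) * weights).sum() / wsum * px)
        out.append(FocusRecord(
            channel=channel_img.channel,
            nucleus_label=nucleus.label,
            pixels=np.column_stack([rows + r0, cols + c0]),
            area_px=int(area),
            centroid_um=(cx, cy),
            peak_intensity=float(weights.max()),
        ))
    out.sort(key=lambda f: (int(f.pixels[0, 0]), int(f.pixels[0, 1])))
    return out


def detect_foci_well(
    channel_img: ImagePlane,
    nuclei: list[NucleusRecord],
    p: FociParams | None = None,
    presmoothed: bool = False,
) -> dict[int, list[FocusRecord]]:
    """Detect foci for every nucleus of a well; returns label -> foci."""
    p = p or FociParams()
    img = channel_img if presmoothed else smooth_channel(channel_img, p)
    return {nuc.label: detect_foci(img, nuc, p) for nuc in nuclei}
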