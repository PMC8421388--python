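"""Image-level processing: background, stitching, alignment, segmentation.

The processing order mirrors a standard high-content survival workflow:
median background subtraction per image, montage stitching of tiles,
translation-only registration across timepoints, soma segmentation on the
morphology channel with a minimum object size of 100 px, and per-object
intensity feature extraction into a flat CSV schema. Segmentation is biased
toward the bright soma rather than the neurites — neurite masks routinely
merge neighbouring cells and dilute the intensity ratio, so a tight soma
mask is what the ratio readout needs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from skimage import filters, measure
from skimage.registration import phase_cross_correlation

__all__ = [
    "FrameImage",
    "SegmentedObject",
    "SegmentationParams",
    "subtract_background",
    "stitch_montage",
    "align_timepoints",
    "segment",
    "extract_features",
    "quantify_masked_area",
    "roi_ratio",
    "features_to_frame",
    "FEATURE_COLUMNS",
]

FEATURE_COLUMNS = [
    "well", "timepoint_h", "object_label", "area_px",
    "centroid_x", "centroid_y",
    "mean_gedi", "mean_morph", "peak_gedi", "peak_morph",
]

MIN_SOMA_AREA_PX = 100  # minimum object size for a soma


@dataclass
class FrameImage:
    """One channel-timepoint intensity grid.

    ``pixels`` is a 2-D float array of finite, non-negative intensities;
    ``channel`` is one of ``gedi``/``morphology``/``aux``; ``tile`` indexes
    the montage position as (row, col).
    """

    pixels: np.ndarray
    well: str = ""
    timepoint: float = 0.0
    channel: str = "morphology"
    tile: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels must be finite")

    def with_pixels(self, pixels: np.ndarray) -> "FrameImage":
        return FrameImage(pixels, self.well, self.timepoint, self.channel, self.tile)

    @classmethod
    def from_tiff(cls, path: str | Path, **meta) -> "FrameImage":
        return cls(tifffile.imread(path).astype(float), **meta)

    def to_tiff(self, path: str | Path) -> None:
        tifffile.imwrite(path, np.clip(self.pixels, 0, 65535).astype(np.uint16))


@dataclass
class SegmentedObject:
    """One segmented neuron: mask geometry plus per-channel intensities."""

    label: int
    well: str
    timepoint: float
    area_px: int
    centroid: tuple[float, float]  # (x, y), 0-based pixel coordinates
    mean_intensity: dict[str, float] = field(default_factory=dict)
    peak_intensity: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable knobs of the pluggable soma segmentation operator."""

    min_size: int = MIN_SOMA_AREA_PX
    smooth_sigma: float = 1.0
    otsu_scale: float = 0.5  # fraction of the Otsu level actually applied
    mad_floor_k: float = 8.0  # threshold never below median + k * 1.4826 * MAD
    soma_area_cap: int = 1200  # components above this are re-cut to their core
    core_quantile: float = 0.75


def subtract_background(image: FrameImage) -> FrameImage:
    """Subtract the image's median intensity; clamp negatives to zero.

    The median of a sparse fluorescence image is the background, so the
    pre-clamp result has median ~0. Clamping keeps downstream intensity
    ratios non-negative. Idempotent on images whose median is already 0.
    """
    med = float(np.median(image.pixels))
    return image.with_pixels(np.clip(image.pixels - med, 0, None))


def stitch_montage(tiles: list[FrameImage], grid: tuple[int, int], overlap_px: int = 0) -> FrameImage:
    """Stitch a complete tile grid into one frame, averaging overlap strips.

    Output size is ``(rows*h - (rows-1)*ov, cols*w - (cols-1)*ov)`` for tiles
    of shape (h, w).

    Raises
    ------
    ValueError
        If any grid position is missing or duplicated.
    """
    rows, cols = grid
    by_pos = {t.tile: t for t in tiles}
    missing = [(r, c) for r in range(rows) for c in range(cols) if (r, c) not in by_pos]
    if missing or len(by_pos) != len(tiles):
        raise ValueError(f"incomplete tile set for {rows}x{cols} grid; missing {missing}")
    h, w = by_pos[(0, 0)].pixels.shape
    out_h = rows * h - (rows - 1) * overlap_px
    out_w = cols * w - (cols - 1) * overlap_px
    acc = np.zeros((out_h, out_w))
    weight = np.zeros((out_h, out_w))
    for (r, c), tile in by_pos.items():
        if tile.pixels.shape != (h, w):
            raise ValueError("all tiles must share one shape")
        y0 = r * (h - overlap_px)
        x0 = c * (w - overlap_px)
        acc[y0 : y0 + h, x0 : x0 + w] += tile.pixels
        weight[y0 : y0 + h, x0 : x0 + w] += 1.0
    ref = by_pos[(0, 0)]
    return FrameImage(acc / weight, ref.well, ref.timepoint, ref.channel, (0, 0))


def align_timepoints(series: list[FrameImage], max_shift_px: int = 25) -> list[tuple[int, int]]:
    """Integer (dx, dy) translation of each frame relative to frame 0.

    Estimated by maximum cross-correlation (phase correlation); applying the
    negated shift registers a frame onto frame 0. Shifts beyond
    ``max_shift_px`` are clamped with a warning; featureless (zero-variance)
    frames get (0, 0) with a warning.
    """
    if len(series) < 2:
        raise ValueError("alignment needs at least 2 frames")
    ref = series[0].pixels
    shifts: list[tuple[int, int]] = [(0, 0)]
    for frame in series[1:]:
        if frame.pixels.shape != ref.shape:
            raise ValueError("all frames must share one shape")
        if np.ptp(frame.pixels) == 0 or np.ptp(ref) == 0:
            warnings.warn(
                f"featureless frame at t={frame.timepoint}: assuming zero shift",
                stacklevel=2,
            )
            shifts.append((0, 0))
            continue
        # phase correlation returns the (row, col) shift registering frame→ref;
        # negate to report the frame's displacement relative to frame 0
        (dy, dx), _, _ = phase_cross_correlation(ref, frame.pixels, upsample_factor=1)
        dx, dy = -int(round(dx)), -int(round(dy))
        if abs(dx) > max_shift_px or abs(dy) > max_shift_px:
            warnings.warn(
                f"shift ({dx}, {dy}) at t={frame.timepoint} exceeds cap {max_shift_px}; clamped",
                stacklevel=2,
            )
            dx = int(np.clip(dx, -max_shift_px, max_shift_px))
            dy = int(np.clip(dy, -max_shift_px, max_shift_px))
        shifts.append((dx, dy))
    return shifts


def _soma_core(component_mask: np.ndarray, intensity: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Restrict an oversized component to its bright core pixels.

    The cut quantile is raised beyond ``core_quantile`` when needed so the
    kept core cannot itself exceed the soma area cap (a plateau of equal
    intensities would otherwise survive the quantile intact).
    """
    vals = intensity[component_mask]
    q = max(params.core_quantile, 1.0 - params.soma_area_cap / vals.size)
    cut = np.quantile(vals, q)
    core = component_mask & (intensity >= cut)
    if core.sum() > params.soma_area_cap:
        # the quantile landed inside an intensity plateau; step the cut up to
        # the next level that actually fits under the cap, if one exists
        levels = np.unique(vals)
        counts = np.array([(vals >= lv).sum() for lv in levels])
        fitting = levels[counts <= params.soma_area_cap]
        if fitting.size:
            core = component_mask & (intensity >= fitting[0])
    return core


def segment(
    image: FrameImage,
    params: SegmentationParams | None = None,
) -> tuple[np.ndarray, list[SegmentedObject]]:
    """Soma segmentation of a background-subtracted morphology frame.

    Operator: Gaussian smooth -> threshold at max(otsu_scale * Otsu, robust
    background floor) -> connected components -> size filter at
    ``params.min_size`` (100 px by default). Otsu alone bisects background
    and the brightest somata, amputating the dim skirt of fading debris, so
    a fraction of the Otsu level (default one half) is applied instead; the
    floor is median + k * 1.4826 * MAD, so a noise-only frame — where any
    Otsu-derived cut would split the noise in half — yields no objects. Components larger than the soma cap are re-cut to pixels above
    a high quantile of their own intensity and re-labeled, keeping the mask
    tight around the bright soma instead of the neurites.

    Returns the label image and per-object geometry (intensity features are
    added separately by :func:`extract_features`). An empty image yields an
    empty result — not an error.
    """
    params = params or SegmentationParams()
    pix = image.pixels
    smoothed = filters.gaussian(pix, sigma=params.smooth_sigma, preserve_range=True)
    if np.ptp(smoothed) == 0:
        return np.zeros(pix.shape, dtype=int), []
    med = float(np.median(smoothed))
    mad = float(np.median(np.abs(smoothed - med)))
    floor = med + params.mad_floor_k * 1.4826 * mad
    thresh = max(params.otsu_scale * filters.threshold_otsu(smoothed), floor)
    binary = smoothed > thresh
    labels = measure.label(binary, connectivity=2)

    # soma bias: oversized components are re-cut to their bright core
    recut = np.zeros_like(binary)
    keep = np.zeros_like(binary)
    for region in measure.regionprops(labels):
        mask = labels == region.label
        if region.area > params.soma_area_cap:
            recut |= _soma_core(mask, smoothed, params)
        else:
            keep |= mask
    labels = measure.label(keep | recut, connectivity=2)

    objects: list[SegmentedObject] = []
    final = np.zeros_like(labels)
    next_label = 1
    for region in measure.regionprops(labels):
        if region.area < params.min_size:
            continue
        cy, cx = region.centroid
        final[labels == region.label] = next_label
        objects.append(
            SegmentedObject(
                label=next_label,
                well=image.well,
                timepoint=image.timepoint,
                area_px=int(region.area),
                centroid=(float(cx), float(cy)),
            )
        )
        next_label += 1
    return final, objects


def extract_features(
    label_image: np.ndarray,
    objects: list[SegmentedObject],
    channel_images: dict[str, FrameImage],
) -> list[SegmentedObject]:
    """Per-object mean and peak intensity within the mask, per channel.

    Channel images must be background-subtracted and registered to the label
    image. Missing channels raise; objects are updated in place and returned.
    """
    for obj in objects:
        mask = label_image == obj.label
        for channel, frame in channel_images.items():
            if frame.pixels.shape != label_image.shape:
                raise ValueError(f"channel {channel!r} shape mismatch with label image")
            vals = frame.pixels[mask]
            obj.mean_intensity[channel] = float(vals.mean()) if vals.size else 0.0
            obj.peak_intensity[channel] = float(vals.max()) if vals.size else 0.0
    return objects


def features_to_frame(objects: list[SegmentedObject]) -> pd.DataFrame:
    """Flatten SegmentedObjects into the fixed per-object CSV schema."""
    rows = [
        {
            "well": o.well, "timepoint_h": o.timepoint, "object_label": o.label,
            "area_px": o.area_px, "centroid_x": o.centroid[0], "centroid_y": o.centroid[1],
            "mean_gedi": o.mean_intensity.get("gedi", np.nan),
            "mean_morph": o.mean_intensity.get("morphology", np.nan),
            "peak_gedi": o.peak_intensity.get("gedi", np.nan),
            "peak_morph": o.peak_intensity.get("morphology", np.nan),
        }
        for o in objects
    ]
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


def quantify_masked_area(
    series: list[FrameImage],
    exclusion_mask: np.ndarray | None = None,
    binarize_threshold: float | None = None,
) -> np.ndarray:
    """Total signal area per timepoint, normalised to the first timepoint.

    Each frame is background-subtracted, the exclusion mask zeroed out, and
    the rest binarised; foreground pixel counts are divided by the count at
    t0 (so the series starts at 1 by construction). The threshold defaults to
    Otsu computed on the t0 frame and is reused for every timepoint — a
    per-frame threshold would confound area trends with intensity trends.

    Raises
    ------
    ValueError
        If the first timepoint has zero foreground area.
    """
    if not series:
        raise ValueError("empty series")
    processed = []
    for frame in series:
        pix = subtract_background(frame).pixels
        if exclusion_mask is not None:
            pix = np.where(exclusion_mask, 0.0, pix)
        processed.append(pix)
    if binarize_threshold is None:
        binarize_threshold = float(filters.threshold_otsu(processed[0]))
    counts = np.array([(p > binarize_threshold).sum() for p in processed], dtype=float)
    if counts[0] == 0:
        raise ValueError("zero foreground area at the first timepoint; cannot normalise")
    return counts / counts[0]


def roi_ratio(channel_images: dict[str, FrameImage], roi_mask: np.ndarray) -> float:
    """Mean GEDI over mean morphology intensity inside one ROI.

    Both channels are background-subtracted first. Used where single somata
    cannot be resolved and the ratio is taken per anatomical region instead.

    Raises
    ------
    ValueError
        If the mask is empty or the morphology mean is non-positive.
    """
    if not np.any(roi_mask):
        raise ValueError("roi_mask selects no pixels")
    gedi = subtract_background(channel_images["gedi"]).pixels[roi_mask].mean()
    morph = subtract_background(channel_images["morphology"]).pixels[roi_mask].mean()
    if morph <= 0:
        raise ValueError("morphology mean is non-positive; ratio undefined")
    return float(gedi / morph)
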