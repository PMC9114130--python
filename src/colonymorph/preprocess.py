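"""Colony segmentation and standardization.

The extraction pipeline mirrors standard practice for single-colony plate
photographs: (i) Canny edge detection finds object boundaries, (ii) a
circular Hough transform locates the largest approximately circular object
(taken to encompass the colony) and everything outside that circle is
masked, (iii) the foreground inside the circle is binarized (Otsu) and its
convex hull becomes the colony mask, capturing the true, non-circular
boundary.  Finally the masked colony is cropped, padded to a square (so the
shape is preserved) and resized to a fixed 100x100 frame.

All parameters are hand-tunable; the defaults here were chosen for the
synthetic generator's 256x256 canvas and work for typical single-colony
crops.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
import numpy as np
from skimage.feature import canny
from skimage.filters import threshold_otsu
from skimage.morphology import convex_hull_image
from skimage.transform import hough_circle, resize

logger = logging.getLogger("colonymorph.preprocess")

__all__ = [
    "PreprocessParams",
    "SegmentationResult",
    "SegmentationError",
    "CircleDetectionError",
    "detect_edges",
    "find_colony_circle",
    "extract_colony",
    "standardize_image",
    "segment_frame",
]


class SegmentationError(RuntimeError):
    """Colony extraction failed for a frame."""


class CircleDetectionError(SegmentationError):
    """No circular object could be located; adjust edge/Hough parameters."""


@dataclass(frozen=True)
class PreprocessParams:
    """Tunables of the segmentation pipeline.

    Canny hysteresis thresholds are quantiles of the gradient magnitude;
    the Hough radius range is a fraction of the smaller image dimension.
    """

    canny_sigma: float = 2.0
    canny_low_quantile: float = 0.60
    canny_high_quantile: float = 0.90
    hough_radius_fractions: tuple[float, float] = (0.10, 0.45)
    hough_radius_step: int = 1
    hough_downscale: int = 2
    hough_rel_threshold: float = 0.9
    hough_support_floor: float = 0.5
    out_size: int = 100


@dataclass
class SegmentationResult:
    """Mask, detected circle and standardized frame for one photograph."""

    mask: np.ndarray
    circle: tuple[float, float, float]  # (cx, cy, r)
    masked: np.ndarray = field(repr=False)
    standardized: np.ndarray | None = field(default=None, repr=False)
    standardized_mask: np.ndarray | None = field(default=None, repr=False)


def detect_edges(
    image: np.ndarray,
    sigma: float = 2.0,
    low_thr: float = 0.60,
    high_thr: float = 0.90,
) -> np.ndarray:
    """Canny edge map; thresholds are gradient-magnitude quantiles.

    A constant image yields an empty edge map (not an error).
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    image = np.asarray(image, dtype=float)
    if np.ptp(image) == 0:
        return np.zeros(image.shape, dtype=bool)
    return canny(
        image,
        sigma=sigma,
        low_threshold=low_thr,
        high_threshold=high_thr,
        use_quantiles=True,
    )


def find_colony_circle(
    edge_map: np.ndarray,
    radius_range: tuple[float, float] | None = None,
    radius_step: int = 1,
    rel_threshold: float = 0.9,
    support_floor: float | None = None,
) -> tuple[float, float, float]:
    """Locate the largest approximately circular object via the Hough transform.

    Returns ``(cx, cy, r)``.  The normalized accumulator measures the
    fraction of each candidate circle's perimeter backed by edge pixels.
    Candidates are the cells within ``rel_threshold`` of the peak; if
    ``support_floor`` is given and the peak reaches it, every cell at or
    above the floor is a candidate instead — any circle with that much
    perimeter support is a real object.  Among candidates the *largest
    radius* wins (the colony boundary is the outermost circular structure,
    and surface texture can produce strong inner rings), then the highest
    accumulator value, then the smallest ``(cy, cx)``.
    """
    edge_map = np.asarray(edge_map, dtype=bool)
    if not edge_map.any():
        raise CircleDetectionError(
            "empty edge map: no circular object to detect; "
            "lower the Canny thresholds or sigma"
        )
    if not (0 < rel_threshold <= 1):
        raise ValueError("rel_threshold must lie in (0, 1]")
    h, w = edge_map.shape
    if radius_range is None:
        radius_range = (0.10 * min(h, w), 0.45 * min(h, w))
    r_min, r_max = radius_range
    if not (0 < r_min < r_max < min(h, w) / 2):
        raise ValueError(f"invalid radius range {radius_range} for shape {(h, w)}")
    radii = np.arange(int(math.ceil(r_min)), int(math.floor(r_max)) + 1, radius_step)
    accum = hough_circle(edge_map, radii)
    best = accum.max()
    if support_floor is not None and best >= support_floor:
        thresh = support_floor
    else:
        thresh = rel_threshold * best
    cand = np.argwhere(accum >= thresh)  # rows of (radius_idx, cy, cx)
    order = sorted(
        cand.tolist(),
        key=lambda rcyx: (-radii[rcyx[0]], -accum[rcyx[0], rcyx[1], rcyx[2]], rcyx[1], rcyx[2]),
    )
    ri, cy, cx = order[0]
    return float(cx), float(cy), float(radii[ri])


def extract_colony(
    image: np.ndarray, circle: tuple[float, float, float]
) -> SegmentationResult:
    """Mask outside the circle, binarize the interior, take the convex hull.

    The mask is the convex hull of the Otsu-bright pixels inside the
    detected circle; output background pixels are set to 0.  The Otsu
    threshold is computed over the whole image so it separates colony from
    background — computed over the circle interior alone it would split the
    colony's own texture (bright folds vs dark troughs) and clip the
    boundary.
    """
    image = np.asarray(image, dtype=float)
    cx, cy, r = circle
    h, w = image.shape
    yy, xx = np.ogrid[0:h, 0:w]
    incircle = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
    if not incircle.any():
        raise SegmentationError("detected circle lies outside the image")
    if np.ptp(image[incircle]) == 0:
        raise SegmentationError("no foreground inside the circle (constant region)")
    thr = threshold_otsu(image)
    fg = incircle & (image >= thr)
    if not fg.any():
        raise SegmentationError("no foreground inside the circle after thresholding")
    # offset_coordinates=False keeps the rasterized hull exactly idempotent
    mask = convex_hull_image(fg, offset_coordinates=False)
    # a colony should fill a sizeable part of its bounding circle; a nearly
    # empty hull means the circle landed on background clutter
    if mask.sum() < 0.3 * np.pi * r**2:
        raise SegmentationError(
            f"foreground hull covers {mask.sum() / (np.pi * r ** 2):.1%} of the "
            "detected circle; circle likely spurious"
        )
    return SegmentationResult(
        mask=mask, circle=(float(cx), float(cy), float(r)), masked=np.where(mask, image, 0.0)
    )


def standardize_image(
    seg: SegmentationResult, out_size: int = 100
) -> tuple[np.ndarray, np.ndarray]:
    """Crop to the mask, pad to a square, resize to ``out_size`` squared.

    Padding (with a robust dark background fill, the 5th percentile of the
    background intensities) keeps the colony's aspect ratio through the
    resize.  Returns the standardized image and its resized mask, and stores
    both on ``seg``.
    """
    mask = seg.mask
    if not mask.any():
        raise SegmentationError("empty mask cannot be standardized")
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1
    crop = seg.masked[r0:r1, c0:c1].astype(float)
    mcrop = mask[r0:r1, c0:c1]
    bg = seg.masked[~mask]
    pad_val = float(np.percentile(bg, 5)) if bg.size else 0.0
    crop = np.where(mcrop, crop, pad_val)
    hh, ww = crop.shape
    side = max(hh, ww)
    py, px = side - hh, side - ww
    pads = ((py // 2, py - py // 2), (px // 2, px - px // 2))
    sq = np.pad(crop, pads, constant_values=pad_val)
    msq = np.pad(mcrop, pads, constant_values=False)
    std = resize(sq, (out_size, out_size), order=1, anti_aliasing=True)
    std_mask = resize(msq.astype(float), (out_size, out_size), order=0, anti_aliasing=False) > 0.5
    seg.standardized = std
    seg.standardized_mask = std_mask
    return std, std_mask


def segment_frame(image: np.ndarray, params: PreprocessParams = PreprocessParams()) -> SegmentationResult:
    """Full per-frame pipeline: edges -> circle -> hull mask -> 100x100 frame.

    Circle detection runs on a ``hough_downscale``-fold subsampled copy of
    the image (the Hough accumulator dominates the cost and the colony
    boundary is a large structure); the detected circle is scaled back to
    full resolution before masking and hull construction.
    """
    ds = max(1, int(params.hough_downscale))
    small = image[::ds, ::ds] if ds > 1 else image
    edges = detect_edges(
        small,
        sigma=max(1.0, params.canny_sigma / ds),
        low_thr=params.canny_low_quantile,
        high_thr=params.canny_high_quantile,
    )
    h, w = small.shape
    lo, hi = params.hough_radius_fractions
    cx, cy, r = find_colony_circle(
        edges,
        radius_range=(lo * min(h, w), hi * min(h, w)),
        radius_step=params.hough_radius_step,
        rel_threshold=params.hough_rel_threshold,
        support_floor=params.hough_support_floor,
    )
    circle = (cx * ds, cy * ds, r * ds)
    seg = extract_colony(image, circle)
    standardize_image(seg, out_size=params.out_size)
    return seg
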