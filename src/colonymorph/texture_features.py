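"""Rotation-invariant uniform LBP texture histograms and the LBP-space PCA.

Each pixel of a (standardized) colony frame is compared with 8 neighbours
sampled on a circle of radius ``radius_px``; a neighbour at least as bright
as the centre contributes bit 1.  If the circular bit pattern is *uniform*
(at most two 0<->1 transitions around the ring) its category is the number
of set bits (0..8); every other pattern falls into the catch-all category 9.
The relative frequencies of the 10 categories over an image form its point
in LBP space; spatial arrangement is integrated out, which is what makes
the feature robust to colony growth.

Sampling convention
-------------------
By default neighbours are sampled at the *nearest pixel* to each circle
position (for radius 1 this is the classic 3x3 ring).  Nearest sampling
makes two invariances exact, not approximate: histograms are unchanged by
90-degree image rotations (on the common interior) and by any strictly
increasing intensity remapping, because only raw pixel comparisons enter
the code.  Bilinear circle sampling (as in
``skimage.feature.local_binary_pattern``) is available via
``sampling="bilinear"``; it breaks exact monotone-remap invariance because
interpolation does not commute with nonlinear remaps.

The per-frame histograms of an ensemble are pooled and reduced with PCA
(mean-centred SVD); three modes suffice to describe most of the variation
in practice, and each frame is then a 3-vector.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

logger = logging.getLogger("colonymorph.features")

__all__ = [
    "N_CATEGORIES",
    "LBPParams",
    "LBPHistogram",
    "FeatureBasis",
    "lbp_code",
    "lbp_image",
    "lbp_histogram",
    "enumerate_pattern_categories",
    "fit_lbp_basis",
    "project",
]

N_CATEGORIES = 10  # 9 uniform categories (0..8) + catch-all 9


@dataclass(frozen=True)
class LBPParams:
    n_neighbors: int = 8
    radius_px: float = 1.0
    sampling: str = "nearest"  # "nearest" | "bilinear"

    def __post_init__(self) -> None:
        if self.n_neighbors != 8:
            raise ValueError("the 10-category scheme requires n_neighbors = 8")
        if self.radius_px <= 0:
            raise ValueError("radius_px must be > 0")
        if self.sampling not in ("nearest", "bilinear"):
            raise ValueError("sampling must be 'nearest' or 'bilinear'")

    @property
    def margin(self) -> int:
        return int(math.ceil(self.radius_px))


@dataclass
class LBPHistogram:
    """Relative frequencies of the 10 LBP categories over one frame."""

    freqs: np.ndarray
    n_pixels_counted: int

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.shape != (N_CATEGORIES,):
            raise ValueError("an LBP histogram has exactly 10 bins")
        if self.n_pixels_counted > 0 and abs(self.freqs.sum() - 1.0) > 1e-9:
            raise ValueError("frequencies must sum to 1")


def _circle_offsets(params: LBPParams) -> tuple[np.ndarray, np.ndarray]:
    # Neighbour i sits at angle 2*pi*i/P, row offset -R*sin, col offset R*cos
    # (the convention of skimage's implementation, so the bilinear mode
    # matches it bit for bit).
    i = np.arange(params.n_neighbors, dtype=float)
    rr = -params.radius_px * np.sin(2 * np.pi * i / params.n_neighbors)
    cc = params.radius_px * np.cos(2 * np.pi * i / params.n_neighbors)
    return rr, cc


def _categorize(bits: np.ndarray) -> np.ndarray:
    """Map stacked neighbour bits (P, ...) to categories 0..9."""
    transitions = (bits != np.roll(bits, -1, axis=0)).sum(axis=0)
    ones = bits.sum(axis=0)
    return np.where(transitions <= 2, ones, 9).astype(np.uint8)


def _bilinear(image: np.ndarray, r: float, c: float) -> float:
    r0, c0 = int(math.floor(r)), int(math.floor(c))
    fr, fc = r - r0, c - c0
    v00 = image[r0, c0]
    v01 = image[r0, c0 + 1] if fc else v00
    v10 = image[r0 + 1, c0] if fr else v00
    v11 = image[r0 + 1, c0 + 1] if (fr and fc) else v00
    return (
        v00 * (1 - fr) * (1 - fc)
        + v01 * (1 - fr) * fc
        + v10 * fr * (1 - fc)
        + v11 * fr * fc
    )


def lbp_code(image: np.ndarray, row: int, col: int, params: LBPParams = LBPParams()) -> int:
    """LBP category (0..9) of a single interior pixel.

    Raises ``IndexError`` if any sampled neighbour would fall out of bounds;
    callers must restrict to the valid interior.
    """
    image = np.asarray(image, dtype=float)
    h, w = image.shape
    m = params.margin
    if not (m <= row < h - m and m <= col < w - m):
        raise IndexError(
            f"pixel ({row}, {col}) has out-of-bounds neighbours at radius {params.radius_px}"
        )
    rr, cc = _circle_offsets(params)
    center = image[row, col]
    if params.sampling == "nearest":
        samples = image[np.round(row + rr).astype(int), np.round(col + cc).astype(int)]
    else:
        samples = np.array([_bilinear(image, row + dr, col + dc) for dr, dc in zip(rr, cc)])
    return int(_categorize((samples >= center).astype(np.uint8)))


def lbp_image(image: np.ndarray, params: LBPParams = LBPParams()) -> np.ndarray:
    """Per-pixel LBP categories for the valid interior; the margin is -1."""
    image = np.asarray(image, dtype=float)
    h, w = image.shape
    m = params.margin
    if h <= 2 * m or w <= 2 * m:
        raise ValueError("image smaller than the LBP neighbourhood")
    out = np.full((h, w), -1, dtype=np.int8)
    rr, cc = _circle_offsets(params)
    center = image[m : h - m, m : w - m]
    if params.sampling == "nearest":
        bits = np.empty((params.n_neighbors,) + center.shape, dtype=np.uint8)
        for i, (dr, dc) in enumerate(zip(np.round(rr).astype(int), np.round(cc).astype(int))):
            nb = image[m + dr : h - m + dr or None, m + dc : w - m + dc or None]
            bits[i] = nb >= center
        out[m : h - m, m : w - m] = _categorize(bits)
    else:
        import warnings

        from skimage.feature import local_binary_pattern

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # float input warning
            codes = local_binary_pattern(
                image, params.n_neighbors, params.radius_px, method="uniform"
            )
        out[m : h - m, m : w - m] = codes[m : h - m, m : w - m].astype(np.int8)
    return out


def lbp_histogram(
    image: np.ndarray,
    mask: np.ndarray | None = None,
    params: LBPParams = LBPParams(),
) -> LBPHistogram:
    """Category frequencies over the mask's valid-interior pixels.

    A pixel is counted iff its centre lies in the mask and its full
    neighbourhood is in-bounds; neighbours may sample outside the mask.
    """
    image = np.asarray(image, dtype=float)
    codes = lbp_image(image, params)
    counted = codes >= 0
    if mask is not None:
        counted &= np.asarray(mask, dtype=bool)
    n = int(counted.sum())
    if n == 0:
        raise ValueError("no countable pixels: mask empty after interior restriction")
    hist = np.bincount(codes[counted].astype(np.int64), minlength=N_CATEGORIES)
    return LBPHistogram(freqs=hist / n, n_pixels_counted=n)


def enumerate_pattern_categories() -> np.ndarray:
    """Category of each of the 256 possible 8-neighbour sign patterns.

    Enumerates every bit pattern directly from the definition; useful as a
    structural check that exactly 10 categories exist (58 patterns are
    uniform).
    """
    bits = ((np.arange(256)[:, None] >> np.arange(8)[None, :]) & 1).astype(np.uint8)
    return _categorize(bits.T)


# ---------------------------------------------------------------------------
# LBP-space PCA


@dataclass
class FeatureBasis:
    """Mean and orthonormal PCA modes fitted on pooled LBP histograms."""

    mean: np.ndarray
    modes: np.ndarray  # (k, 10), orthonormal rows
    explained_variance_ratio: np.ndarray

    @property
    def k(self) -> int:
        return self.modes.shape[0]


def fit_lbp_basis(histograms: Sequence[np.ndarray] | np.ndarray, k: int = 3) -> FeatureBasis:
    """Mean-centred SVD of the pooled histograms; top-k right singular vectors.

    The sign of each mode is fixed so its largest-magnitude entry is
    positive.  If the data have rank < k, fewer modes are returned with a
    warning.
    """
    H = np.asarray(
        [h.freqs if isinstance(h, LBPHistogram) else h for h in histograms], dtype=float
    )
    if H.ndim != 2 or H.shape[1] != N_CATEGORIES:
        raise ValueError("histograms must be an (n, 10) array")
    if H.shape[0] < k + 1:
        raise ValueError(f"need at least {k + 1} histograms to fit {k} modes")
    mean = H.mean(axis=0)
    X = H - mean
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    tol = max(X.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    rank = int((s > tol).sum())
    if rank < k:
        logger.warning("histogram matrix has rank %d < k=%d; returning %d modes", rank, k, rank)
        k = rank
    modes = vt[:k].copy()
    for row in modes:
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1
    total = float((s**2).sum())
    evr = (s[:k] ** 2) / total if total > 0 else np.zeros(k)
    return FeatureBasis(mean=mean, modes=modes, explained_variance_ratio=evr)


def project(histogram: np.ndarray | LBPHistogram, basis: FeatureBasis) -> np.ndarray:
    """Coordinates of histogram(s) in the PCA basis: (h - mean) @ modes.T."""
    if isinstance(histogram, LBPHistogram):
        histogram = histogram.freqs
    h = np.asarray(histogram, dtype=float)
    if h.shape[-1] != basis.mean.shape[0]:
        raise ValueError(f"expected last dimension {basis.mean.shape[0]}, got {h.shape[-1]}")
    return (h - basis.mean) @ basis.modes.T
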