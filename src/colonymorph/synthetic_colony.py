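"""Seeded synthetic colony time-lapse generator.

Emulates the statistical structure the analysis pipeline assumes: a roughly
circular colony on a noisy darker background, photographed at irregular
timestamps, with a surface texture (ridges, lumps or craters) that develops
as the colony grows.  It makes no attempt at biophysical realism — it exists
so every downstream stage (segmentation, LBP texture scoring, trajectory
assembly, clustering) can be exercised with known ground truth.

Texture classes
---------------
smooth
    Flat disk; ``amplitude`` may be 0.
ridged
    Concentric sinusoidal rings, intensity ∝ 1 + a·sin(2π·f·r).
lumpy
    A field of bright Gaussian bumps scattered inside the disk; bump
    positions are fixed in colony-relative coordinates so the texture grows
    coherently outward with the colony.
cratered
    The lumpy field with negated sign (dark pits).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .io_formats import ColonyKey, ColonyRecord, format_colony_filename

__all__ = [
    "TextureSpec",
    "GrowthSpec",
    "TEXTURE_CLASSES",
    "texture_preset",
    "render_frame",
    "logistic_radius",
    "generate_colony_series",
    "generate_ensemble",
    "write_ensemble",
]

TEXTURE_CLASSES = ("smooth", "ridged", "lumpy", "cratered")

#: Mean intensity of the colony disk (image scale [0, 1]).
DISK_INTENSITY = 0.7
#: Background mean, as a fraction of the disk intensity.
BACKGROUND_FRACTION = 0.25


@dataclass(frozen=True)
class TextureSpec:
    """Surface-texture class and its parameters.

    ``spatial_frequency`` is in cycles per pixel along the radius: it sets
    the ring spacing for *ridged* and the bump size (sigma = 1/(4f) px) for
    *lumpy*/*cratered*.  ``amplitude`` is the relative intensity modulation.
    """

    class_name: str
    amplitude: float = 0.0
    spatial_frequency: float = 0.08
    noise_sd: float = 0.02

    def __post_init__(self) -> None:
        if self.class_name not in TEXTURE_CLASSES:
            raise ValueError(f"unknown texture class {self.class_name!r}")
        if not (self.amplitude >= 0 and math.isfinite(self.amplitude)):
            raise ValueError("amplitude must be finite and >= 0")
        if not (self.spatial_frequency > 0 and math.isfinite(self.spatial_frequency)):
            raise ValueError("spatial_frequency must be finite and > 0")
        if not (self.noise_sd >= 0 and math.isfinite(self.noise_sd)):
            raise ValueError("noise_sd must be finite and >= 0")


#: Frozen study-condition presets for the four texture classes.
_PRESETS = {
    "smooth": TextureSpec("smooth", amplitude=0.0),
    "ridged": TextureSpec("ridged", amplitude=0.35, spatial_frequency=0.08),
    "lumpy": TextureSpec("lumpy", amplitude=0.5, spatial_frequency=0.05),
    # craters are finer-grained than bumps as well as inverted in sign
    "cratered": TextureSpec("cratered", amplitude=0.5, spatial_frequency=0.09),
}


def texture_preset(class_name: str, **overrides) -> TextureSpec:
    return replace(_PRESETS[class_name], **overrides)


@dataclass(frozen=True)
class GrowthSpec:
    """Colony growth and imaging-cadence parameters.

    Defaults mirror the acquisition statistics of the real experiments: a
    median of one photograph every 23 minutes over 3 days.  ``sampling_jitter``
    is the half-width of the uniform multiplicative jitter on the interval
    between frames; ``dropout_prob`` independently drops frames (the first is
    always kept).
    """

    initial_radius_px: float = 30.0
    final_radius_px: float = 90.0
    duration_hours: float = 72.0
    sampling_median_minutes: float = 23.0
    sampling_jitter: float = 0.3
    dropout_prob: float = 0.1

    def __post_init__(self) -> None:
        if self.initial_radius_px <= 0:
            raise ValueError("initial_radius_px must be > 0")
        if self.final_radius_px < self.initial_radius_px:
            raise ValueError("final_radius_px must be >= initial_radius_px")
        if self.duration_hours <= 0 or self.sampling_median_minutes <= 0:
            raise ValueError("duration and sampling median must be > 0")
        if not (0 <= self.dropout_prob < 1):
            raise ValueError("dropout_prob must lie in [0, 1)")
        if not (0 <= self.sampling_jitter < 1):
            raise ValueError("sampling_jitter must lie in [0, 1)")


def _texture_field(
    rr: np.ndarray,
    yy: np.ndarray,
    xx: np.ndarray,
    radius_px: float,
    texture: TextureSpec,
    tex_rng: np.random.Generator,
) -> np.ndarray:
    """Relative intensity modulation (zero-mean-ish) inside the disk."""
    if texture.class_name == "smooth" or texture.amplitude == 0:
        return np.zeros_like(rr)
    if texture.class_name == "ridged":
        return texture.amplitude * np.sin(2 * np.pi * texture.spatial_frequency * rr)
    # lumpy / cratered: impulses at fixed colony-relative positions, one
    # shared Gaussian blur.  sigma is fixed in pixels (surface features keep
    # their physical size as the colony grows).
    sigma = 1.0 / (4.0 * texture.spatial_frequency)
    # enough bumps to tile the final extent; density ~0.3 bumps per sigma^2
    n_bumps = max(8, int(round(0.3 * (radius_px / sigma) ** 2)))
    # draw a fixed pool from the per-colony texture stream, use the first n
    pool = 4 * max(n_bumps, int(round(0.3 * (2.5 * radius_px / sigma) ** 2)))
    u = tex_rng.random((pool, 2))
    ang = 2 * np.pi * u[:, 0]
    rad = np.sqrt(u[:, 1])  # uniform over the unit disk
    py = rad[:n_bumps] * np.sin(ang[:n_bumps]) * radius_px
    px = rad[:n_bumps] * np.cos(ang[:n_bumps]) * radius_px
    impulses = np.zeros_like(rr)
    iy = np.clip(np.round(py - yy[0, 0]).astype(int), 0, rr.shape[0] - 1)
    ix = np.clip(np.round(px - xx[0, 0]).astype(int), 0, rr.shape[1] - 1)
    np.add.at(impulses, (iy, ix), 1.0)
    field = gaussian_filter(impulses, sigma) * (2 * np.pi * sigma**2)
    field = texture.amplitude * np.clip(field, 0, 1.5)
    if texture.class_name == "cratered":
        field = -field
    return field


def render_frame(
    radius_px: float,
    texture: TextureSpec,
    image_size: int = 256,
    rng_seed: int | Sequence[int] = 0,
    texture_seed: int | Sequence[int] | None = None,
    angle_deg: float = 0.0,
    plate_edge: bool = False,
) -> np.ndarray:
    """Render one synthetic photograph (float32 in [0, 1]).

    The frame is a pure function of its arguments.  ``rng_seed`` drives the
    pixel noise; ``texture_seed`` (default: derived from ``rng_seed``) drives
    bump placement, so a colony's texture can stay coherent across frames
    while per-frame noise differs.  ``angle_deg`` rotates the texture about
    the colony centre (for rotation-invariance experiments).
    """
    if radius_px >= image_size / 2:
        raise ValueError(f"radius {radius_px} px does not fit a {image_size} px canvas")
    rng = np.random.default_rng(rng_seed)
    if texture_seed is not None:
        tex_rng = np.random.default_rng(texture_seed)
    else:
        tex_rng = np.random.default_rng(int(rng.integers(0, 2**31)))
    c = (image_size - 1) / 2.0
    yy, xx = np.mgrid[0:image_size, 0:image_size].astype(np.float64)
    yy -= c
    xx -= c
    if angle_deg:
        th = np.deg2rad(angle_deg)
        yy, xx = np.cos(th) * yy - np.sin(th) * xx, np.sin(th) * yy + np.cos(th) * xx
    rr = np.hypot(yy, xx)
    disk = rr <= radius_px
    img = np.full((image_size, image_size), DISK_INTENSITY * BACKGROUND_FRACTION)
    inside = DISK_INTENSITY * (1.0 + _texture_field(rr, yy, xx, radius_px, texture, tex_rng))
    img[disk] = inside[disk]
    if plate_edge:
        arc_r = 0.47 * image_size
        arc = (np.abs(rr - arc_r) < 1.0) & (xx > 0)
        img[arc] = 0.05
    if texture.noise_sd > 0:
        img = img + rng.normal(0.0, texture.noise_sd, img.shape)
    return np.clip(img, 0.0, 1.0).astype(np.float32)


def logistic_radius(t_hours: float | np.ndarray, growth: GrowthSpec) -> np.ndarray:
    """Colony radius along a symmetric logistic from initial to final size.

    The midpoint sits at half the duration, where the radius equals the
    arithmetic mean of the initial and final radii exactly; the steepness is
    fixed so the curve covers ~98.7% of the radius span within the duration.
    """
    t = np.asarray(t_hours, dtype=float)
    r0, rf, T = growth.initial_radius_px, growth.final_radius_px, growth.duration_hours
    if rf == r0:
        return np.full_like(t, r0)
    k = 10.0 / T
    return r0 + (rf - r0) / (1.0 + np.exp(-k * (t - T / 2.0)))


def _sample_times(growth: GrowthSpec, rng: np.random.Generator) -> list[int]:
    times: list[float] = []
    t = 0.0
    horizon = growth.duration_hours * 60.0
    while t <= horizon + 1e-9:
        times.append(t)
        step = growth.sampling_median_minutes
        if growth.sampling_jitter > 0:
            step *= 1.0 + growth.sampling_jitter * (2.0 * rng.random() - 1.0)
        t += step
    minutes = [int(round(x)) for x in times]
    # jitter rounding could in principle collide; enforce strict increase
    out = [minutes[0]]
    for m in minutes[1:]:
        out.append(max(m, out[-1] + 1))
    return out


def generate_colony_series(
    growth: GrowthSpec,
    texture: TextureSpec,
    key: ColonyKey,
    seed: int | Sequence[int],
    image_size: int = 256,
    rotate_frames: bool = False,
    plate_edge: bool = False,
) -> ColonyRecord:
    """Generate one colony's time-lapse as a :class:`ColonyRecord`.

    The radius follows :func:`logistic_radius`; the texture amplitude ramps
    in linearly with radius between the initial and final size, so young
    colonies of every class look alike and diverge as they grow.  Per-frame
    RNG streams are derived from ``(seed, frame index)`` so dropping a frame
    does not shift the appearance of the others.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    time_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=ss.entropy, spawn_key=ss.spawn_key + (0, 0xA0))
    )
    times = _sample_times(growth, time_rng)
    keep = [i == 0 or time_rng.random() >= growth.dropout_prob for i in range(len(times))]
    texture_seed = np.random.SeedSequence(entropy=ss.entropy, spawn_key=ss.spawn_key + (0, 0xC0))
    frames: list[tuple[int, np.ndarray]] = []
    span = growth.final_radius_px - growth.initial_radius_px
    for idx, t in enumerate(times):
        if not keep[idx]:
            continue
        r = float(logistic_radius(t / 60.0, growth))
        ramp = (r - growth.initial_radius_px) / span if span > 0 else 1.0
        tex = replace(texture, amplitude=texture.amplitude * float(np.clip(ramp, 0.0, 1.0)))
        frame_seed = np.random.SeedSequence(entropy=ss.entropy, spawn_key=ss.spawn_key + (1, idx))
        angle = float(time_rng.integers(0, 360)) if rotate_frames else 0.0
        frames.append(
            (
                t,
                render_frame(
                    r,
                    tex,
                    image_size=image_size,
                    rng_seed=frame_seed,
                    texture_seed=texture_seed,
                    angle_deg=angle,
                    plate_edge=plate_edge,
                ),
            )
        )
    return ColonyRecord(key=key, frames=frames, folder="synthetic")


#: Relative half-width of the per-colony uniform jitter applied to growth and
#: texture parameters by :func:`generate_ensemble` — replicate colonies of one
#: strain are biologically variable, not clones of a single parameter set.
REPLICATE_CV = 0.1


def perturb_colony_specs(
    growth: GrowthSpec,
    texture: TextureSpec,
    rng: np.random.Generator,
    cv: float = REPLICATE_CV,
) -> tuple[GrowthSpec, TextureSpec]:
    """Per-replicate parameter jitter: each rate/size/amplitude is scaled by
    an independent uniform factor in [1-cv, 1+cv]."""

    def f() -> float:
        return 1.0 + cv * (2.0 * rng.random() - 1.0)

    g = replace(
        growth,
        initial_radius_px=growth.initial_radius_px * f(),
        final_radius_px=max(growth.initial_radius_px, growth.final_radius_px * f()),
        duration_hours=growth.duration_hours * f(),
    )
    t = replace(
        texture,
        amplitude=texture.amplitude * f(),
        spatial_frequency=texture.spatial_frequency * f(),
        noise_sd=texture.noise_sd * f(),
    )
    return g, t


def generate_ensemble(
    class_specs: Sequence[tuple[TextureSpec, int]],
    growth: GrowthSpec,
    seed: int,
    image_size: int = 256,
    base_strain_id: int = 11000,
    replicate_cv: float = REPLICATE_CV,
    rotate_frames: bool = False,
    plate_edge: bool = False,
) -> tuple[list[ColonyRecord], np.ndarray]:
    """Generate a labelled ensemble: ``count`` colonies per texture class.

    Returns the records and the planted integer class labels (one per
    record, in record order) for recovery tests.  Per-colony seeds are
    derived deterministically from the master seed, and each replicate's
    growth/texture parameters are jittered by ``replicate_cv``.
    """
    records: list[ColonyRecord] = []
    labels: list[int] = []
    colony_index = 0
    for class_idx, (texture, count) in enumerate(class_specs):
        if count < 1:
            raise ValueError("class counts must be >= 1")
        for rep in range(count):
            key = ColonyKey(strain_id=base_strain_id + class_idx, iteration=rep + 1)
            colony_seed = np.random.SeedSequence(entropy=seed, spawn_key=(colony_index,))
            jitter_rng = np.random.default_rng(
                np.random.SeedSequence(entropy=seed, spawn_key=(colony_index, 0xB10))
            )
            g, t = perturb_colony_specs(growth, texture, jitter_rng, cv=replicate_cv)
            records.append(
                generate_colony_series(
                    g, t, key, colony_seed, image_size=image_size,
                    rotate_frames=rotate_frames, plate_edge=plate_edge,
                )
            )
            labels.append(class_idx)
            colony_index += 1
    return records, np.asarray(labels)


def write_ensemble(
    records: Sequence[ColonyRecord],
    out_dir: Path | str,
    folder: str = "synthetic-Cam1",
    ext: str = "jpg",
) -> Path:
    """Write an ensemble to disk in the dataset's folder/filename layout."""
    import imageio.v3 as iio

    target = Path(out_dir) / folder
    target.mkdir(parents=True, exist_ok=True)
    for rec in records:
        for t, img in rec.frames:
            name = format_colony_filename(rec.key, t, ext=ext)
            iio.imwrite(target / name, (np.clip(img, 0, 1) * 255).astype(np.uint8))
    return target
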