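"""Feature-space growth trajectories on a common hourly grid.

Frames arrive at irregular timestamps, so per-frame 3-D feature points are
binned to a shared uniform grid (multiple frames in a bin are averaged),
interior gaps are filled by linear interpolation, and bins after a colony's
last observation are filled by holding its final value constant — growth is
assumed to have saturated.  The grid's final time is the median over
colonies of the last observation time, which is robust to failed-growth
experiments that end early.

The distance between two colonies is the mean over grid bins of the
Euclidean distance between their 3-D feature points — a metric, computed
directly between trajectories with no model fitted in between.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .io_formats import ColonyKey, ColonyRecord, CondensedDistances

__all__ = [
    "EnsembleGrid",
    "FeatureTrajectory",
    "bin_series",
    "build_common_grid",
    "fill_trajectory",
    "trajectory_distance",
    "pairwise_distances",
]


@dataclass(frozen=True)
class EnsembleGrid:
    """Uniform time grid shared by every colony of an ensemble."""

    t_final_hours: float
    bin_hours: float = 1.0

    def __post_init__(self) -> None:
        if self.bin_hours <= 0 or self.t_final_hours < 0:
            raise ValueError("bin width must be > 0 and final time >= 0")

    @property
    def n_bins(self) -> int:
        return int(np.floor(self.t_final_hours / self.bin_hours + 1e-9)) + 1

    @property
    def bin_starts_hours(self) -> np.ndarray:
        return np.arange(self.n_bins) * self.bin_hours

    def bin_index(self, t_hours: np.ndarray) -> np.ndarray:
        return np.floor(np.asarray(t_hours, dtype=float) / self.bin_hours + 1e-9).astype(int)


@dataclass
class FeatureTrajectory:
    """One colony's 3-coordinate series on the ensemble grid.

    ``observed[b]`` is True where bin ``b`` holds binned data and False where
    the value was filled by interpolation or saturation extrapolation.
    """

    key: ColonyKey
    grid: EnsembleGrid
    coords: np.ndarray = field(repr=False)
    observed: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.observed = np.asarray(self.observed, dtype=bool)
        n = self.grid.n_bins
        if self.coords.shape[0] != n or self.observed.shape != (n,):
            raise ValueError("coords/observed must span the whole grid")
        if not self.observed.any():
            raise ValueError(f"{self.key.root_name}: trajectory has no observed bin")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"{self.key.root_name}: non-finite coordinates after filling")


def bin_series(
    times_minutes: np.ndarray, points: np.ndarray, bin_hours: float = 1.0
) -> list[tuple[int, np.ndarray]]:
    """Average the feature points falling into each time bin.

    Returns (bin index, mean point) for the occupied bins, in time order.
    """
    t = np.asarray(times_minutes, dtype=float)
    p = np.atleast_2d(np.asarray(points, dtype=float))
    if t.size == 0:
        raise ValueError("cannot bin an empty series")
    if np.any(np.diff(t) < 0):
        raise ValueError("timestamps must be sorted ascending")
    if p.shape[0] != t.size:
        raise ValueError("times and points disagree in length")
    idx = np.floor(t / 60.0 / bin_hours + 1e-9).astype(int)
    out = []
    for b in np.unique(idx):
        out.append((int(b), p[idx == b].mean(axis=0)))
    return out


def build_common_grid(
    records: Iterable[ColonyRecord | float], bin_hours: float = 1.0
) -> EnsembleGrid:
    """Grid ending at the median of the colonies' last observation times.

    Accepts colony records or raw last-times in hours.  With an even number
    of colonies the lower median is used; the result is rounded down to a
    bin boundary.
    """
    last_hours = sorted(
        (r.last_time_minutes / 60.0 if isinstance(r, ColonyRecord) else float(r))
        for r in records
    )
    if not last_hours:
        raise ValueError("need at least one colony")
    med = last_hours[(len(last_hours) - 1) // 2]
    t_final = np.floor(med / bin_hours + 1e-9) * bin_hours
    return EnsembleGrid(t_final_hours=float(t_final), bin_hours=bin_hours)


def fill_trajectory(
    binned: Sequence[tuple[int, np.ndarray]],
    grid: EnsembleGrid,
    key: ColonyKey | None = None,
) -> FeatureTrajectory:
    """Spread binned points over the grid, filling the gaps.

    Interior gaps: linear interpolation per coordinate.  Bins after the last
    observation: the last observed value held constant (saturation).  Bins
    before the first observation: the first observed value held.  Binned
    points beyond the grid end are ignored.
    """
    if not binned:
        raise ValueError("need at least one binned observation")
    n = grid.n_bins
    dim = np.asarray(binned[0][1]).shape[0]
    coords = np.full((n, dim), np.nan)
    observed = np.zeros(n, dtype=bool)
    for b, v in binned:
        if 0 <= b < n:
            coords[b] = v
            observed[b] = True
    if not observed.any():
        raise ValueError("no observation falls inside the grid")
    obs_idx = np.flatnonzero(observed)
    all_idx = np.arange(n)
    for d in range(dim):
        # np.interp holds edge values constant outside the observed span
        coords[:, d] = np.interp(all_idx, obs_idx, coords[obs_idx, d])
    return FeatureTrajectory(
        key=key if key is not None else ColonyKey(0, 0, prefix="X"),
        grid=grid,
        coords=coords,
        observed=observed,
    )


def trajectory_distance(
    a: FeatureTrajectory, b: FeatureTrajectory, mode: str = "mean"
) -> float:
    """Mean (default) or sum over bins of the per-bin Euclidean distance."""
    if a.grid != b.grid:
        raise ValueError("trajectories are not on the same grid")
    if mode not in ("mean", "sum"):
        raise ValueError("mode must be 'mean' or 'sum'")
    d = np.linalg.norm(a.coords - b.coords, axis=1)
    return float(d.mean() if mode == "mean" else d.sum())


def pairwise_distances(
    trajectories: Sequence[FeatureTrajectory], mode: str = "mean"
) -> CondensedDistances:
    """All n(n-1)/2 trajectory distances, condensed, in input order."""
    if len(trajectories) < 2:
        raise ValueError("need at least two trajectories")
    grid = trajectories[0].grid
    for t in trajectories[1:]:
        if t.grid != grid:
            raise ValueError("all trajectories must share one grid")
    X = np.stack([t.coords for t in trajectories])  # (n, T, 3)
    n = X.shape[0]
    chunks = []
    for i in range(n - 1):
        d = np.linalg.norm(X[i + 1 :] - X[i], axis=2)  # (n-i-1, T)
        chunks.append(d.mean(axis=1) if mode == "mean" else d.sum(axis=1))
    return CondensedDistances(
        ids=[t.key.root_name for t in trajectories], values=np.concatenate(chunks)
    )
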