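"""On-disk conventions for colony time-lapse datasets.

A dataset is a directory of experiment folders (named for acquisition date
and camera, e.g. ``2014-10-23-Cam1``), each holding JPEG/PNG frames named
``<PREFIX><STRAIN>_<ITER>_<MINUTES>.jpg``.  Two CSV schemas travel with the
images: a *coordinates table* (one row per frame, with its three PCA-mode
coordinates in LBP space) and a *distances table* (the condensed pairwise
trajectory-distance matrix).  This module parses and writes all of them.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform

logger = logging.getLogger("colonymorph.io")

__all__ = [
    "ColonyKey",
    "ColonyRecord",
    "CondensedDistances",
    "FilenameParseError",
    "SchemaError",
    "parse_colony_filename",
    "format_colony_filename",
    "parse_root_name",
    "scan_image_dataset",
    "load_image",
    "read_coordinates_table",
    "write_coordinates_table",
    "read_distances_table",
    "write_distances_table",
    "COORDINATES_COLUMNS",
    "DISTANCES_COLUMNS",
]

COORDINATES_COLUMNS = [
    "Folder",
    "Filename",
    "Time",
    "PCA mode 1",
    "PCA mode 2",
    "PCA mode 3",
]
DISTANCES_COLUMNS = ["I", "J", "I Root Filename", "J Root Filename", "Distance"]

_FILENAME_RE = re.compile(
    r"^(?P<prefix>[A-Za-z]+)(?P<strain>\d+)_(?P<iteration>\d+)_(?P<time>\d+)"
    r"\.(?P<ext>jpe?g|png)$",
    re.IGNORECASE,
)
_ROOT_RE = re.compile(r"^(?P<prefix>[A-Za-z]+)(?P<strain>\d+)_(?P<iteration>\d+)$")


class FilenameParseError(ValueError):
    """A colony image filename does not follow the dataset convention."""


class SchemaError(ValueError):
    """A CSV table does not carry the expected columns."""


@dataclass(frozen=True, order=True)
class ColonyKey:
    """Identity of one colony experiment iteration.

    ``strain_id`` selects the strain (e.g. 11407), ``iteration`` the replicate
    on the plate; ``prefix`` records the growth-medium prefix of the filename
    (``YPG`` in the published data).  The canonical ``root_name`` zero-pads
    the iteration to three digits.
    """

    strain_id: int
    iteration: int
    prefix: str = "YPG"

    @property
    def root_name(self) -> str:
        return f"{self.prefix}{self.strain_id}_{self.iteration:03d}"


def parse_root_name(root: str) -> ColonyKey:
    m = _ROOT_RE.match(root)
    if m is None:
        raise FilenameParseError(f"root name {root!r} is not <PREFIX><digits>_<digits>")
    return ColonyKey(
        strain_id=int(m.group("strain")),
        iteration=int(m.group("iteration")),
        prefix=m.group("prefix"),
    )


def parse_colony_filename(name: str) -> tuple[ColonyKey, int]:
    """Split ``YPG11407_001_1080.jpg`` into its key and timestamp (minutes).

    Raises :class:`FilenameParseError` naming the offending component when the
    name does not match ``<PREFIX><digits>_<digits>_<digits>.jpg``.
    """
    m = _FILENAME_RE.match(name)
    if m is None:
        # Be specific about what is missing where we can.
        stem = name.rsplit(".", 1)[0]
        parts = stem.split("_")
        if len(parts) < 3:
            raise FilenameParseError(
                f"{name!r}: expected <PREFIX><STRAIN>_<ITER>_<MINUTES>.<ext>, "
                f"missing timestamp or iteration field"
            )
        raise FilenameParseError(f"{name!r}: malformed colony image filename")
    key = ColonyKey(
        strain_id=int(m.group("strain")),
        iteration=int(m.group("iteration")),
        prefix=m.group("prefix"),
    )
    return key, int(m.group("time"))


def format_colony_filename(key: ColonyKey, timestamp_minutes: int, ext: str = "jpg") -> str:
    return f"{key.root_name}_{timestamp_minutes}.{ext}"


@dataclass
class ColonyRecord:
    """One colony experiment iteration: ordered, timestamped frames."""

    key: ColonyKey
    frames: list[tuple[int, np.ndarray]]
    folder: str | None = None

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError(f"{self.key.root_name}: a colony record needs >= 1 frame")
        times = [t for t, _ in self.frames]
        if any(t < 0 for t in times):
            raise ValueError(f"{self.key.root_name}: negative timestamp")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError(f"{self.key.root_name}: timestamps must strictly increase")

    @property
    def times_minutes(self) -> np.ndarray:
        return np.array([t for t, _ in self.frames], dtype=float)

    @property
    def last_time_minutes(self) -> int:
        return self.frames[-1][0]


def load_image(path: Path | str) -> np.ndarray:
    """Load an image as a 2-D float array in [0, 1] (luminance for RGB)."""
    import imageio.v3 as iio
    from skimage.color import rgb2gray
    from skimage.util import img_as_float

    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = rgb2gray(arr[..., :3])
    return img_as_float(arr)


def scan_image_dataset(root_dir: Path | str) -> list[ColonyRecord]:
    """Group the image files under ``root_dir`` into time-sorted colony records.

    Frames are grouped by (experiment folder, root name); files that fail to
    parse or load are skipped with a warning, as is the lexicographically
    later of two files sharing a (root name, timestamp).
    """
    root = Path(root_dir)
    groups: dict[tuple[str, str], dict[int, str]] = {}
    keys: dict[tuple[str, str], ColonyKey] = {}
    files = sorted(p for p in root.rglob("*") if p.is_file())
    if not files:
        logger.warning("no image files found under %s", root)
        return []
    for path in files:
        try:
            key, t = parse_colony_filename(path.name)
        except FilenameParseError as exc:
            logger.warning("skipping %s: %s", path, exc)
            continue
        folder = str(path.parent.relative_to(root)) if path.parent != root else "."
        gk = (folder, key.root_name)
        bucket = groups.setdefault(gk, {})
        keys[gk] = key
        if t in bucket:
            logger.warning(
                "duplicate timestamp %d for %s: keeping %s, skipping %s",
                t, key.root_name, bucket[t], path.name,
            )
            continue
        bucket[t] = str(path)
    records: list[ColonyRecord] = []
    for gk in sorted(groups):
        folder, _root_name = gk
        frames: list[tuple[int, np.ndarray]] = []
        for t in sorted(groups[gk]):
            try:
                frames.append((t, load_image(groups[gk][t])))
            except Exception as exc:  # unreadable image: skip, keep going
                logger.warning("unreadable image %s: %s", groups[gk][t], exc)
        if frames:
            records.append(ColonyRecord(key=keys[gk], frames=frames, folder=folder))
    return records


# ---------------------------------------------------------------------------
# Coordinates table (one row per frame, three PCA-mode coordinates)

def write_coordinates_table(df: pd.DataFrame, path: Path | str) -> None:
    missing = [c for c in COORDINATES_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"coordinates table missing columns {missing}; expected {COORDINATES_COLUMNS}")
    df.loc[:, COORDINATES_COLUMNS].to_csv(path, index=False)


def read_coordinates_table(path: Path | str) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in COORDINATES_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}; expected header {COORDINATES_COLUMNS}")
    return df.loc[:, COORDINATES_COLUMNS]


# ---------------------------------------------------------------------------
# Condensed distances

@dataclass
class CondensedDistances:
    """Pairwise colony distances stored in condensed (upper-triangle) form.

    ``ids`` orders the colonies; ``values`` follows the scipy ``squareform``
    convention, i.e. entry for pair (i, j), i < j, sits at
    ``i * n - i * (i + 1) // 2 + (j - i - 1)``.
    """

    ids: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        n = len(self.ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (n * (n - 1) // 2,):
            raise ValueError(
                f"expected {n*(n-1)//2} condensed entries for {n} ids, got {self.values.shape}"
            )
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValueError("distances must be finite and non-negative")

    @property
    def n(self) -> int:
        return len(self.ids)

    def distance(self, i: int, j: int) -> float:
        if i == j:
            return 0.0
        i, j = min(i, j), max(i, j)
        return float(self.values[i * self.n - i * (i + 1) // 2 + (j - i - 1)])

    def iter_pairs(self) -> Iterator[tuple[int, int, float]]:
        k = 0
        for i in range(self.n - 1):
            for j in range(i + 1, self.n):
                yield i, j, float(self.values[k])
                k += 1

    def to_square(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    @classmethod
    def from_square(cls, square: np.ndarray, ids: Sequence[str]) -> "CondensedDistances":
        square = np.asarray(square, dtype=float)
        if square.ndim != 2 or square.shape[0] != square.shape[1]:
            raise ValueError("square distance matrix must be 2-D square")
        if not np.allclose(square, square.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(square), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")
        return cls(ids=list(ids), values=squareform(square, checks=False))


def condensed_to_square(cd: CondensedDistances) -> np.ndarray:
    return cd.to_square()


def square_to_condensed(square: np.ndarray, ids: Sequence[str]) -> CondensedDistances:
    return CondensedDistances.from_square(square, ids)


def write_distances_table(cd: CondensedDistances, path: Path | str) -> None:
    """Write the condensed distances in the published five-column CSV schema."""
    rows = [
        (i, j, cd.ids[i], cd.ids[j], d)
        for i, j, d in cd.iter_pairs()
    ]
    pd.DataFrame(rows, columns=DISTANCES_COLUMNS).to_csv(path, index=False)


def read_distances_table(path: Path | str) -> CondensedDistances:
    df = pd.read_csv(path)
    missing = [c for c in DISTANCES_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}; expected header {DISTANCES_COLUMNS}")
    idx: dict[str, int] = {}
    for _, row in df.iterrows():
        idx.setdefault(row["I Root Filename"], int(row["I"]))
        idx.setdefault(row["J Root Filename"], int(row["J"]))
    ids = [name for name, _ in sorted(idx.items(), key=lambda kv: kv[1])]
    if [idx[name] for name in ids] != list(range(len(ids))):
        raise SchemaError(f"{path}: indices are not a contiguous 0-based range")
    n = len(ids)
    values = np.full(n * (n - 1) // 2, np.nan)
    for _, row in df.iterrows():
        i, j = int(row["I"]), int(row["J"])
        i, j = min(i, j), max(i, j)
        values[i * n - i * (i + 1) // 2 + (j - i - 1)] = float(row["Distance"])
    if np.any(np.isnan(values)):
        raise SchemaError(f"{path}: not all {n*(n-1)//2} pairs are present")
    return CondensedDistances(ids=ids, values=values)
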