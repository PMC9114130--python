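"""End-to-end orchestration: simulate -> preprocess -> features -> distances -> cluster.

Two entry points are provided.  :func:`run_pipeline` is the disk-based path
used by the CLI: every stage reads and writes the dataset CSV schemas, a
manifest records the config hash, seed and per-stage row counts, and stages
are resumable — if a stage's output CSV already exists in the run directory
it is loaded instead of recomputed.  :func:`run_synthetic_study` is the
in-memory path used by tests and the acceptance script: it streams frames
through segmentation and LBP scoring one colony at a time, so image arrays
never accumulate.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io_formats, preprocess, prototype_clustering, synthetic_colony, trajectories
from .config import PipelineConfig
from .io_formats import ColonyKey, ColonyRecord, CondensedDistances, format_colony_filename
from .texture_features import LBPParams, fit_lbp_basis, lbp_histogram, project

logger = logging.getLogger("colonymorph.pipeline")

__all__ = ["StudyResult", "run_synthetic_study", "run_pipeline", "colony_histograms",
           "coordinates_from_records", "trajectories_from_coordinates", "cluster_distances"]


def colony_histograms(
    record: ColonyRecord,
    params: preprocess.PreprocessParams = preprocess.PreprocessParams(),
    lbp: LBPParams = LBPParams(),
) -> tuple[list[int], list[np.ndarray]]:
    """Segment and LBP-score every frame of one colony.

    Frames whose segmentation fails are dropped with a warning (imputation
    happens later, in feature space).  Returns kept timestamps and their
    10-bin histograms.
    """
    times: list[int] = []
    hists: list[np.ndarray] = []
    for t, img in record.frames:
        try:
            seg = preprocess.segment_frame(img, params)
            h = lbp_histogram(seg.standardized, seg.standardized_mask, lbp)
        except (preprocess.SegmentationError, ValueError) as exc:
            logger.warning("%s t=%d: frame dropped (%s)", record.key.root_name, t, exc)
            continue
        times.append(t)
        hists.append(h.freqs)
    return times, hists


def coordinates_from_records(
    records: Sequence[ColonyRecord],
    params: preprocess.PreprocessParams = preprocess.PreprocessParams(),
    lbp: LBPParams = LBPParams(),
    n_modes: int = 3,
) -> pd.DataFrame:
    """Coordinates table (one row per frame) from raw colony records.

    The PCA basis is fitted on every frame of every colony pooled, then each
    frame is projected onto the retained modes.
    """
    rows: list[tuple] = []
    all_hists: list[np.ndarray] = []
    for rec in records:
        times, hists = colony_histograms(rec, params, lbp)
        for t, h in zip(times, hists):
            rows.append((rec.folder or ".", format_colony_filename(rec.key, t), t))
            all_hists.append(h)
    if not all_hists:
        raise RuntimeError("no frame survived segmentation")
    basis = fit_lbp_basis(np.asarray(all_hists), k=n_modes)
    coords = project(np.asarray(all_hists), basis)
    df = pd.DataFrame(rows, columns=["Folder", "Filename", "Time"])
    for m in range(coords.shape[1]):
        df[f"PCA mode {m + 1}"] = coords[:, m]
    return df


def trajectories_from_coordinates(
    df: pd.DataFrame, bin_hours: float = 1.0
) -> list[trajectories.FeatureTrajectory]:
    """Assemble per-colony trajectories on the common grid from a coordinates table."""
    mode_cols = [c for c in df.columns if c.startswith("PCA mode")]
    parsed = df["Filename"].map(io_formats.parse_colony_filename)
    df = df.assign(_root=[k.root_name for k, _ in parsed])
    trajs: list[trajectories.FeatureTrajectory] = []
    last_times = {
        root: sub["Time"].max() / 60.0 for root, sub in df.groupby("_root", sort=True)
    }
    grid = trajectories.build_common_grid(list(last_times.values()), bin_hours=bin_hours)
    for root, sub in df.groupby("_root", sort=True):
        sub = sub.sort_values("Time")
        binned = trajectories.bin_series(
            sub["Time"].to_numpy(), sub[mode_cols].to_numpy(), bin_hours=bin_hours
        )
        trajs.append(
            trajectories.fill_trajectory(binned, grid, key=io_formats.parse_root_name(root))
        )
    return trajs


def cluster_distances(
    cd: CondensedDistances,
    trajs: Sequence[trajectories.FeatureTrajectory],
    k_range: tuple[int, int] | None = None,
) -> tuple[prototype_clustering.Dendrogram, prototype_clustering.CutResult]:
    """Minimax-linkage dendrogram plus the CH-selected cut.

    The CH index needs centroids, which exist in trajectory space but not in
    a general metric space, so it is evaluated on the flattened trajectory
    vectors (grid length x 3 per colony).
    """
    order = {t.key.root_name: i for i, t in enumerate(trajs)}
    X = np.stack([trajs[order[r]].coords.ravel() for r in cd.ids])
    dendro = prototype_clustering.minimax_linkage(cd)
    cut = prototype_clustering.select_cut(dendro, X, k_range=k_range)
    return dendro, cut


@dataclass
class StudyResult:
    """Everything the in-memory pipeline produces for one ensemble."""

    coordinates: pd.DataFrame
    trajectories: list
    distances: CondensedDistances
    dendrogram: prototype_clustering.Dendrogram
    cut: prototype_clustering.CutResult
    true_labels: np.ndarray | None = None

    @property
    def prototype_roots(self) -> list[str]:
        return [self.distances.ids[leaf] for leaf in self.cut.prototypes.values()]


def run_synthetic_study(
    class_specs: Sequence[tuple[synthetic_colony.TextureSpec, int]],
    growth: synthetic_colony.GrowthSpec,
    seed: int,
    image_size: int = 256,
    params: preprocess.PreprocessParams = preprocess.PreprocessParams(),
    lbp: LBPParams = LBPParams(),
    n_modes: int = 3,
    bin_hours: float = 1.0,
    distance_mode: str = "mean",
    k_range: tuple[int, int] | None = None,
) -> StudyResult:
    """Generate a labelled synthetic ensemble and run the full pipeline on it.

    Colonies are generated and reduced to LBP histograms one at a time to
    keep memory flat; the PCA basis is then fitted on the pooled histograms.
    """
    rows: list[tuple] = []
    all_hists: list[np.ndarray] = []
    labels: list[int] = []
    colony_index = 0
    for class_idx, (texture, count) in enumerate(class_specs):
        for rep in range(count):
            key = ColonyKey(strain_id=11000 + class_idx, iteration=rep + 1)
            colony_seed = np.random.SeedSequence(entropy=seed, spawn_key=(colony_index,))
            jitter_rng = np.random.default_rng(
                np.random.SeedSequence(entropy=seed, spawn_key=(colony_index, 0xB10))
            )
            g, tex = synthetic_colony.perturb_colony_specs(growth, texture, jitter_rng)
            rec = synthetic_colony.generate_colony_series(
                g, tex, key, colony_seed, image_size=image_size
            )
            times, hists = colony_histograms(rec, params, lbp)
            if not times:
                raise RuntimeError(f"{key.root_name}: every frame failed segmentation")
            for t, h in zip(times, hists):
                rows.append((rec.folder, format_colony_filename(key, t), t))
                all_hists.append(h)
            labels.append(class_idx)
            colony_index += 1
    basis = fit_lbp_basis(np.asarray(all_hists), k=n_modes)
    coords = project(np.asarray(all_hists), basis)
    df = pd.DataFrame(rows, columns=["Folder", "Filename", "Time"])
    for m in range(coords.shape[1]):
        df[f"PCA mode {m + 1}"] = coords[:, m]
    trajs = trajectories_from_coordinates(df, bin_hours=bin_hours)
    cd = trajectories.pairwise_distances(trajs, mode=distance_mode)
    dendro, cut = cluster_distances(cd, trajs, k_range=k_range)
    # records were generated class-by-class in sorted key order, matching the
    # sorted root-name order of the trajectories
    return StudyResult(
        coordinates=df,
        trajectories=trajs,
        distances=cd,
        dendrogram=dendro,
        cut=cut,
        true_labels=np.asarray(labels),
    )


def four_class_study(seed: int, colonies_per_class: int = 12) -> StudyResult:
    """The package's reference synthetic study: one ensemble per texture class.

    Twelve replicate colonies of each of the four texture classes (smooth,
    ridged, lumpy, cratered) are grown for 72 h and photographed every
    ~2 h with 30% interval jitter and 10% frame dropout, then pushed through
    the full pipeline.  The 2 h cadence is a reduced problem size chosen so
    the study runs on a laptop; the texture classes and growth curve are the
    generator presets.
    """
    growth = synthetic_colony.GrowthSpec(
        sampling_median_minutes=120.0,
        duration_hours=72.0,
        sampling_jitter=0.3,
        dropout_prob=0.1,
    )
    specs = [
        (synthetic_colony.texture_preset(c), colonies_per_class)
        for c in synthetic_colony.TEXTURE_CLASSES
    ]
    return run_synthetic_study(specs, growth, seed=seed)


# ---------------------------------------------------------------------------
# Disk-based, resumable pipeline (CLI)


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_mapping(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, run_dir: Path | str) -> Path:
    """Execute every stage, writing the dataset schemas into ``run_dir``.

    Stage outputs: ``images/`` (simulate), ``coordinates.csv``,
    ``distances.csv``, ``linkage.csv``, ``clusters.csv``, ``ch_curve.csv``
    and ``manifest.json``.  Existing ``coordinates.csv``/``distances.csv``
    are reused (resume) rather than recomputed.
    """
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": _config_hash(config),
        "master_seed": config.master_seed,
        "stages": {},
    }

    def stage(name):
        t0 = time.perf_counter()

        def done(**counts):
            manifest["stages"][name] = {"seconds": round(time.perf_counter() - t0, 3), **counts}
            logger.info("stage %s done in %.2fs %s", name, time.perf_counter() - t0, counts)

        return done

    coords_path = run_dir / "coordinates.csv"
    dist_path = run_dir / "distances.csv"

    if not coords_path.exists():
        images_dir = Path(config.input_dir) if config.input_dir else run_dir / "images"
        if config.simulate is not None and config.input_dir is None:
            done = stage("simulate")
            records, labels = synthetic_colony.generate_ensemble(
                list(config.simulate.classes),
                config.simulate.growth,
                seed=config.master_seed,
                image_size=config.simulate.image_size,
                rotate_frames=config.simulate.rotate_frames,
                plate_edge=config.simulate.plate_edge,
            )
            synthetic_colony.write_ensemble(records, images_dir, folder=config.simulate.folder)
            pd.DataFrame(
                {"root_name": [r.key.root_name for r in records], "class": labels}
            ).to_csv(run_dir / "true_labels.csv", index=False)
            done(colonies=len(records), frames=sum(len(r.frames) for r in records))
        done = stage("features")
        records = io_formats.scan_image_dataset(images_dir)
        if not records:
            raise RuntimeError(f"no colony images found under {images_dir}")
        df = coordinates_from_records(
            records, config.preprocess, config.lbp, n_modes=config.n_modes
        )
        io_formats.write_coordinates_table(df, coords_path)
        # the CSV is the stage interface: read it back so a later resumed run
        # starts from bit-identical values
        df = io_formats.read_coordinates_table(coords_path)
        done(frames=len(df), colonies=len(records))
    else:
        logger.info("resuming from existing %s", coords_path)
        df = io_formats.read_coordinates_table(coords_path)

    trajs = trajectories_from_coordinates(df, bin_hours=config.bin_hours)
    if not dist_path.exists():
        done = stage("distances")
        cd = trajectories.pairwise_distances(trajs, mode=config.distance_mode)
        io_formats.write_distances_table(cd, dist_path)
        cd = io_formats.read_distances_table(dist_path)
        done(pairs=len(cd.values), colonies=cd.n)
    else:
        logger.info("resuming from existing %s", dist_path)
        cd = io_formats.read_distances_table(dist_path)

    done = stage("cluster")
    n = cd.n
    k_range = (config.k_min, config.k_max if config.k_max is not None else max(2, min(50, int(np.ceil(np.sqrt(n))))))
    dendro, cut = cluster_distances(cd, trajs, k_range=k_range)
    link = pd.DataFrame(
        [
            (m.left, m.right, m.height, m.size, cd.ids[m.prototype])
            for m in dendro.merges
        ],
        columns=["left", "right", "height", "size", "prototype_root_name"],
    )
    link.to_csv(run_dir / "linkage.csv", index=False)
    proto_leaves = set(cut.prototypes.values())
    pd.DataFrame(
        {
            "root_name": cd.ids,
            "cluster": cut.labels,
            "is_prototype": [i in proto_leaves for i in range(n)],
        }
    ).to_csv(run_dir / "clusters.csv", index=False)
    pd.DataFrame(
        prototype_clustering.ch_curve(dendro, _flat_vectors(cd, trajs), k_range),
        columns=["k", "ch"],
    ).to_csv(run_dir / "ch_curve.csv", index=False)
    done(colonies=n, k_selected=cut.k, ch=cut.ch)

    manifest["selected_k"] = cut.k
    with open(run_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return run_dir


def _flat_vectors(cd: CondensedDistances, trajs) -> np.ndarray:
    order = {t.key.root_name: i for i, t in enumerate(trajs)}
    return np.stack([trajs[order[r]].coords.ravel() for r in cd.ids])
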