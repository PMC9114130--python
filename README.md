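# colonymorph

Quantify and categorize how microbial colony morphology *develops* from
time-lapse photographs.

Yeast colonies grow strain-dependent surface structure — folds, ridges,
lumps, craters — that experts traditionally score by eye.  `colonymorph`
replaces that with an unsupervised pipeline built for time-lapse imagery:

1. **Segment** each photograph: Canny edges → circular Hough transform for
   the colony boundary → convex hull of the thresholded interior → pad and
   resize to a standard 100×100 frame.
2. **Score texture** with the rotation-invariant uniform local binary
   pattern (LBP): each pixel is compared with its 8 ring neighbours, the
   pattern falls into one of 10 categories, and the frame becomes the
   10-vector of category frequencies.  Spatial layout is integrated out, so
   the score is robust to growth; the nearest-pixel sampling used here makes
   it *exactly* invariant to 90° rotations and to any strictly increasing
   intensity remapping.
3. **Reduce** the pooled histograms with PCA (SVD); 3 modes suffice, so each
   frame is a point in a 3-D feature space.
4. **Assemble trajectories** on a common hourly grid (median ending time of
   the ensemble): bin, interpolate interior gaps, and hold the final value
   after a colony's last observation (saturation).  The distance between two
   colonies is the mean over bins of the Euclidean distance between their
   feature points — a metric, with no model fitted in between.
5. **Cluster** with agglomerative hierarchical clustering under **minimax
   linkage**, d(G,H) = min_c max_x dist(c,x) over the merged cluster: every
   cluster comes with a *prototype*, an actual colony whose image series
   represents it.  The dendrogram cut is chosen by the Calinski–Harabasz
   index.

A seeded synthetic-colony generator (circular colony, logistic growth,
controllable texture class, irregular timestamps) makes the whole pipeline
testable end to end without any external data.

## Worked example

Run the whole pipeline on a small simulated two-class ensemble:

```sh
cat > demo.yaml <<EOF
master_seed: 3
simulate:
  classes:
    - {class_name: smooth, count: 2}
    - {class_name: ridged, count: 2}
  growth: {initial_radius_px: 30, final_radius_px: 70, duration_hours: 12,
           sampling_median_minutes: 180, sampling_jitter: 0.2, dropout_prob: 0.0}
k_max: 3
EOF
colonymorph run-all --config demo.yaml --out run/
```

which logs each stage and finishes with

```
INFO colonymorph.pipeline: stage simulate done in 0.11s {'colonies': 4, 'frames': 18}
INFO colonymorph.pipeline: stage features done in 1.09s {'frames': 18, 'colonies': 4}
INFO colonymorph.pipeline: stage distances done in 0.00s {'pairs': 6, 'colonies': 4}
INFO colonymorph.pipeline: stage cluster done in 0.00s {'colonies': 4, 'k_selected': 2, 'ch': 103.8...}
```

`run/` now holds the stage artifacts in the dataset's CSV schemas:
`coordinates.csv` (one row per frame: folder, filename, timestamp in
minutes, and the frame's three PCA-mode coordinates), `distances.csv`
(condensed pairwise trajectory distances: indices, root filenames,
distance), `linkage.csv` (one row per merge: children, height, size and the
prototype's root filename), `clusters.csv` (colony → cluster, with the
prototype flagged), `ch_curve.csv`, and a `manifest.json` recording the
config hash, seed and per-stage counts.  Here `k_selected: 2` means the
CH-chosen cut found the two planted texture classes; `clusters.csv` shows
the two smooth colonies in one cluster and the two ridged colonies in the
other, each represented by one prototype colony.  Re-running with the same
config and seed reproduces every CSV byte for byte, and a run directory
with an existing `coordinates.csv` resumes from it, skipping the image
stages.

The same stages are available individually (`colonymorph simulate /
preprocess / features / distances / cluster`) for working with a real image
dataset laid out as `<experiment-folder>/<STRAIN>_<ITER>_<MINUTES>.jpg`.

Library use mirrors the CLI:

```python
from colonymorph.pipeline import four_class_study
study = four_class_study(seed=1)          # 4 texture classes x 12 colonies
print(study.cut.k)                        # 4
print(study.prototype_roots)              # one representative colony per cluster
```

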