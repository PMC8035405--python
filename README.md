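# osteomix

Quantification of osteoblast–osteoclast spatial intermingling and direct
cell–cell contact from two-channel fluorescence microscopy, together with a
fully ground-truthed synthetic scene generator for validating every stage of
the pipeline.

## Who this is for

Bone biologists and image analysts working with two-reporter intravital or
coculture imaging — e.g. Col2.3-ECFP (cyan, mature osteoblasts) together
with TRAP-tdTomato (red, mature osteoclasts) — who want reproducible,
scriptable answers to three questions:

1. **How intermingled are the two cell populations?** (cell mixture index
   on tiled maximum-intensity projections)
2. **How many osteoblast–osteoclast contacts are there in 3-D**, normalized
   to cell surface area? (colocalization contact counting on z-stacks)
3. **How long do individual contacts last** in time-lapse cocultures?
   (contact-duration tracking)

## The cell mixture index (CMI)

Given the binarized foreground pixels of both channels in a field, each
pixel becomes a point labeled cyan or red. Agglomerative clustering with
Ward's criterion runs on the coordinates alone (colors ignored): starting
from singletons, at each step the pair of clusters A, B minimizing

    Δ(A, B) = |A||B| / (|A| + |B|) · ‖μ_A − μ_B‖²

is merged, until one cluster remains. At every cluster count k the
size-weighted two-class Gini impurity

    I(k) = Σ_c (n_c / N) · (1 − p_cyan,c² − p_red,c²)

is evaluated and normalized by the whole-set impurity g_total = I(1). The
CMI is the trapezoidal area under y(k) = I(k)/g_total plotted against merge
progress x = (N − k)/(N − 1) ∈ [0, 1].

Segregated populations keep their early clusters pure (the curve hugs zero;
CMI → 0), while intermingled populations are impure at every scale (the
curve rises immediately; CMI → 1). Any bichromatic two-point set scores
exactly 0.5; CMI is invariant to label swap, rigid motion and uniform
scaling.

Fields are preprocessed the way tiled intravital mosaics are: stitch,
gamma-correct, one global Otsu threshold per channel, split into 16 tiles,
and analyze only tiles whose red/cyan area ratio lies in [0.5, 2].

## 3-D contacts and 2-D contact durations

- **contacts3d** — per channel: slice-wise four-direction 3×3 Sobel edge
  enhancement, a global Otsu threshold, 26-connected component labeling,
  then exclusion of cyan objects ≤ 125 µm³ and red objects ≤ 1000 µm³
  (unlikely to be cells). Voxels foreground in both retained masks form the
  contact ("yellow") channel; its connected components are contact events,
  reported per µm² of retained cyan and red surface area (exposed-voxel-face
  estimate).
- **timelapse** — per frame: Otsu binarization, 8-connected labeling,
  retention of green objects ≥ 100 µm² and red objects ≥ 1000 µm²
  (excluding vesicles and mononuclear cells). Objects are tracked by
  maximal-overlap association; a contact track follows a (green, red) pair
  while its overlap persists, tolerating up to `max_gap` missing frames, and
  durations are reported in minutes.

## Worked example

Generate one synthetic mosaic at each extreme of the mixing parameter and
score its tiles:

```python
from osteomix.experiments import experiment_scene_config
from osteomix.synthetic import generate_field
from osteomix.cmi import CmiConfig, cmi_for_image

for lam in (0.0, 1.0):
    image, truth = generate_field(experiment_scene_config(mixing_lambda=lam, seed=4))
    table = cmi_for_image(image, CmiConfig(tile_grid=(2, 2), cap=300, seed=0))
    print(f"mixing_lambda = {lam}")
    print(table.round(3).to_string(index=False))
```

Output (columns abridged):

```
mixing_lambda = 0.0
 tile_row  tile_col  cyan_area_px  red_area_px  ratio  passed_filter   cmi
        0         0          1203         2616  2.175          False   NaN
        0         1          1321         2738  2.073          False   NaN
        1         0          1112         1276  1.147           True 0.032
        1         1          4915         2974  0.605           True 0.108

mixing_lambda = 1.0
 tile_row  tile_col  cyan_area_px  red_area_px  ratio  passed_filter   cmi
        0         0          1203         2181  1.813           True 0.192
        0         1          1321         1215  0.920           True 0.318
        1         0          1112         1950  1.754           True 0.245
        1         1          4915         3966  0.807           True 0.343
```

Tiles whose red/cyan area ratio falls outside [0.5, 2] are filtered
(`passed_filter = False`, no CMI). In the fully segregated scene
(λ = 0) the analyzed tiles score 0.03–0.11 — clusters stay single-colored
through most of the merge sequence — while in the fully co-clustered scene
(λ = 1) the same tiles score 0.19–0.34.

The same generator scripts ground-truth contacts, so recovery can be
verified end to end:

```python
from osteomix.experiments import RunConfig, run_contact_experiment
table, summary = run_contact_experiment(n_seeds=10, config=RunConfig(seed=1))
print(summary)
# {'count_recovery_rate': 1.0, 'duration_recovery_rate': 1.0, 'n_seeds': 10}
```

## Command line

One `osteomix` command with sub-commands `simulate`, `cmi`, `contacts3d`,
`track2d` and `experiment`; rasters travel as multi-page TIFF with a JSON
calibration sidecar, tables as CSV. Exit codes: 0 success, 2 configuration
error, 3 data error.

```
osteomix simulate --kind field --mixing-lambda 1.0 --seed 4 --out scene.tif
osteomix cmi --input scene.tif --tile-grid 4x4 --cap 2000 --seed 7 --out results.csv
osteomix contacts3d --input stack.tif --alpha 0.5 --out contacts/
osteomix track2d --input tl.tif --interval-min 8 --out tracks/
```

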