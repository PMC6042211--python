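# locohcv

Time-scaled local convex hull (T-LoCoH) home-range estimation with
cross-validated selection of the two method parameters: the nearest-neighbor
count `k` and the time-scaling factor `s`.

Around every GPS fix, a local convex hull is built from its `k` nearest
neighbors under the linear time-scaled distance

```
TSD(a, b) = sqrt(dx² + dy² + (s · vmax · dt)²)
```

where `vmax` is the track's maximum observed speed. The collection of hulls,
normalized by its **summed** hull area `A` (overlaps double-counted), is read
as a probability density: a location covered by `g` hulls has density `g / A`.
Parameters are selected by cross-validation — each candidate `(k, s)` is scored
by the total natural-log probability of held-out fixes under the training
hullsets,

```
P(k, s) = Σ_splits Σ_test-points log(g / A),      log(1 / A²) if g = 0,
```

and the maximizing pair is found with a three-stage coarse-to-fine grid search
(default: k = 4–800 step 20 and s = 0–0.05 step 0.01; then 40 k values around
the peak in steps of 5; then 10 k values in steps of 1 with s at 0.001
resolution). From the selected hullset the package derives isopleth home-range
polygons plus per-hull revisitation (NSV) and visit-duration (MNLV) metrics.

## Requirements and install

Python ≥ 3.10 with numpy, shapely (≥ 2.0), pandas, click.

```sh
pip install --no-build-isolation -e .
python -m pytest -q tests/        # full suite, ~2 min on one CPU
```

## Input data

Delimited text (comma or tab), one individual per file, default columns
`individual_id,timestamp,x,y`. Timestamps are ISO-8601 or epoch seconds.
**Coordinates must be projected planar meters** — the loader never reprojects,
and Movebank-style geographic columns (`location-long`/`location-lat`) are
rejected with a reminder to project first.

## CLI

```sh
# synthetic multi-patch track (see example TOML below)
locohcv simulate --config sim.toml --out track.csv

# three-stage cross-validated search for (k, s)
locohcv optimize --input track.csv --config cv.toml --out result.json

# isopleth home range + summary at chosen parameters
locohcv homerange --input track.csv --k 171 --s 0.0133 --level 0.95 --ivg 86400 --out hr.geojson

# per-hull NSV/MNLV table
locohcv metrics --input track.csv --k 171 --s 0.0133 --ivg 86400 --out metrics.tsv
```

Every run writes a `*.runrecord.json` sidecar (config snapshot, seed, input
checksums, software version); re-running with an identical record reproduces
byte-identical outputs. Exit codes: 0 success, 1 data/parameter error,
2 usage error.

`cv.toml`:

```toml
ivg = 86400            # inter-visit gap, seconds (no canonical value; document yours)
# vmax = 1.5           # optional override; default = computed from the full track

[split]
mode = "random"        # or "temporal-blocks"
n_splits = 5
test_fraction = 0.25
seed = 1

[search]               # all fields optional; defaults shown in --help / docs
k_min = 4
k_max_grid = 800
s_max = 0.05
```

`sim.toml`:

```toml
patches = [[0.0, 0.0, 150.0], [1000.0, 0.0, 150.0]]   # x, y, radius (m)
schedule = [[0, 100], [1, 100], [0, 100]]             # (patch, dwell fixes)
dt = 600.0
within_patch_sd = 50.0
travel_speed = 1.5
seed = 1
```

## Library

```python
import locohcv as lc

traj = lc.load_trajectory("track.csv")
vmax = lc.compute_vmax(traj)
scheme = lc.SplitScheme(n_splits=5, test_fraction=0.25, seed=1)
coarse, final = lc.optimize(traj, scheme, vmax, lc.SearchConfig())
k, s, score = final.best

hullset = lc.build_hullset(traj, k, s, vmax)
summary = lc.summarize(hullset, level=0.95, ivg=86400.0)
```

## Notes and caveats

- `s = 0` is legal everywhere and reduces the method to the purely spatial
  LoCoH k-method.
- `k` counts the parent fix itself, so a hull is built from exactly `k` points.
- Scoring areas are m²; the `1/A²` fallback is not scale-invariant, so hullsets
  with total area ≤ 1 m² are rejected as degenerate.
- The staged search is a heuristic: on strongly multimodal score surfaces the
  fine stage's ±5 k-window may not reach a distant global optimum.
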