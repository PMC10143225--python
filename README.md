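# stemscan

Basal stem and understory metrics from terrestrial forest point clouds,
with a synthetic scene generator for validation.

Low-cost RGB-D sensors (tablet LiDAR, time-of-flight and stereo depth
cameras) can map the lower few metres of a forest plot, but their SLAM
registration drifts, duplicates stem faces, and smears stem silhouettes
with mixed depth pixels. Benchmarking them against terrestrial laser
scanning (TLS) requires a reproducible measurement pipeline. `stemscan`
implements that pipeline for anyone extracting basal inventory metrics
from terrestrial point clouds — forest researchers, urban-forestry groups,
or sensor evaluators:

- **Ground classification** by the lowest-occupied-voxel (octree) rule or a
  cloth simulation filter (CSF), plus a low-percentile fallback height for
  subplots where understory hides the ground; a gridded terrain model
  provides above-ground heights (AGH).
- **Stem segmentation** by voxel region growing seeded on a PCA
  verticality descriptor, with a finer-voxel refinement pass for merged
  neighbours.
- **Stem measurement**: base position as the component-wise median of the
  basal point band (robust to basal sweep), and diameter at breast height
  (DBH) from a least-squares circle fit through the 1.3 m AGH slice —
  algebraic (Kåsa) initialisation refined by Gauss–Newton minimisation of
  Σ(‖pᵢ − c‖ − r)².
- **Stem proximity and understory load**: distance to the next closest
  stem (flagging pairs inside a device's duplicate-capture radius), and
  per-stem understory cover and volume in device-range subplots using a
  10 mm voxel-column rule: the highest occupied voxel in each column and
  all voxels beneath it count as filled, because upper foliage occludes
  what lies below.
- **Comparison statistics**: RMSE, RMSPE (RMSE as a percentage of the mean
  reference DBH), signed bias, Welch's t, Pearson's r, capture-failure
  summaries, and scatter reports.
- **Synthetic scenes** with exact truth: sinusoidal terrain relief,
  tapered/swept/leaning stems, analytic understory patches, and the three
  RGB-D artifact families (duplicate faces, drift, signed radial
  backscatter), so every stage is testable without field data.

## Worked example

Simulate a two-stem plot and measure it:

```bash
stemscan simulate --config scene.yaml --out scene.ply
stemscan segment scene.ply --device kinect --out-dir out
```

with `scene.yaml`:

```yaml
plot_radius: 5.0
ground_relief_amplitude: 0.1
ground_point_spacing: 0.05
point_spacing: 0.02
seed: 4
stems:
  - {base_xy: [1.5, 0.0], dbh_true: 25.0, height: 2.2}
  - {base_xy: [-1.2, 1.8], dbh_true: 35.0, height: 2.2}
```

prints

```
plot_id  stem_id    base_x   base_y    dbh_cm device capture_status  fit_rms_residual  n_slice_points  arc_coverage_deg  nearest_stem_m  within_duplicate_range
   plot        0 -1.196712 1.801673 35.019999 kinect       captured          0.000141             275        353.454476        3.239073                   False
   plot        1  1.495047 0.000000 25.010261 kinect       captured          0.000143             195        350.764701        3.239073                   False
```

Both stems are recovered within 0.02 cm of their true diameters; the
residual column is the circle-fit RMS in metres, `arc_coverage_deg` shows
the slice sampled nearly the full circumference (single-face captures of
small stems show up here), and at 3.24 m apart neither stem sits inside
the Kinect's 2 m duplicate-capture radius.

The same stages are available as library calls (`generate_scene`,
`octree_ground_segment`, `csf_ground_segment`, `segment_stems`, `fit_dbh`,
`understory_metrics`, `replicate_study`, ...); see the module docstrings
and `docs/methods.md` for the model details and parameter definitions.

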