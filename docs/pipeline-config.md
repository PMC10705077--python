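# Pipeline configuration reference

`osteovasc pipeline --config cfg.yaml [--seed N] [--out-dir DIR]` reads a
YAML mapping with the keys below.  `--seed` overrides every cohort seed
(offset per cohort) so one integer reproduces the whole run.

```yaml
cohorts:                      # one entry per time point
  - time_point: T1            # label used in the statistics design
    seed: 11                  # cohort seed (overridden by --seed)
    groups:
      - label: P              # treatment-arm label
        n_samples: 7          # >= 2
        vessel_radius_factor: 1.0   # (0, 2]; multiplies branch radii near lesions
        effect_distance_um: 700.0   # reach of the radius effect from the lesions
        lesion_count_offset: 0      # added to the base lesion count
        wall_scale: 1.0             # multiplies the cortical wall thickness
    base:                     # phantom spec shared by the cohort (all optional)
      grid_shape: [64, 64, 64]
      voxel_size_um: 3.5      # scalar or [z, y, x], µm
      seed: 0
      shell:       {outer_radius_um: 90.0, wall_thickness_um: 25.0, taper: 0.12}
      trabeculae:  {rod_count: 10, rod_radius_um: 6.0}
      vessels:     {branch_count: 8, radius_range_um: [7.0, 12.0],
                    tortuosity: 0.35, min_length_um: 120.0}
      metastases:  {lesion_count: 2, semi_axis_range_um: [18.0, 38.0]}
      render:      {background_mean: 0.10, marrow_mean: 0.35, bone_mean: 0.65,
                    vessel_mean: 0.90, blur_um: 2.0, noise_sd: 0.02}

out_dir: run_out              # output directory (CSV reports + manifest.json)
voi_thresholds_um: [300, 700, 1000]   # strictly increasing, µm
stats_threshold_um: 700       # which VOI feeds the group comparisons
tv_closing_um: null           # TV closing radius; null = 10 voxels
evaluate_baseline: false      # also render, segment, and write dice.csv
n_montecarlo: 2000            # Lilliefors Monte-Carlo replicates (>= 1000)
segmenter:                    # optional; keys of SegmenterParams
  smoothing_um: 1.0
  envelope_closing_um: 30.0
```

Outputs in `out_dir`: `morphometry.csv` (one row per sample and scope),
`cohort_table.csv` (long form: sample, time point, group, metric, value),
`stats.csv` (ANOVA rows with their Lilliefors/Bartlett assumption checks),
optionally `dice.csv`, and `manifest.json` (tool version, config echo, seeds,
SHA-256 checksums of every output).  Rerunning an identical config and seed
reproduces the CSVs byte for byte.

The same `groups`/`base` mapping is accepted by `osteovasc cohort --config`,
and the `base` phantom mapping alone by `osteovasc phantom --config`.
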