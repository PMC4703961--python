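# File formats

## HDF5 photon cubes (`*.h5`)

One file per rendered scene (or acquisition), both channels:

```
/nadh/counts        uint32, shape (y, x, t)
/fad/counts         uint32, shape (y, x, t)
/irf/samples        float64, shape (t,), sums to 1
/truth/cell_labels      int32, shape (y, x)      [simulated data only]
/truth/nucleus_labels   int32, shape (y, x)
/truth/cytoplasm_labels int32, shape (y, x)
/truth/cells            bytes (CSV of the ground-truth per-cell table)
```

Root attributes: `bin_width_ps`, `n_bins`, `pixel_size_um`, `irf_fwhm_ps`.

## Parameter maps (`*.ome.tiff` + `.json` sidecar)

Multi-page float32 OME-TIFF, page order `alpha1, tau1, tau2, tau_m,
intensity, chi2, bin_radius, mask`; masked (unfit) pixels are NaN in every
parameter page.  The JSON sidecar records the page names, channel and the
fit configuration used.

## Label maps (`*.ome.tiff` + `.json` sidecar)

Three-page 16-bit TIFF: cells, nuclei, cytoplasms; background 0, label sets
agree across pages, nucleus k ⊂ cell k.  Sidecar holds `pixel_size_um`.

## Per-cell tables (`cells.csv`)

One row per cell: ids (`cell_id`, `organoid_id`), group key (`sample`,
`preparation`, `recovery_days`, `treatment`, `timepoint_hr`), endpoints
(`nadh_intensity`, `fad_intensity`, `redox_ratio`, `nadh_tau_m`,
`fad_tau_m`, `nadh_alpha1`, `nadh_tau1`, `nadh_tau2`, `fad_alpha1`,
`fad_tau1`, `fad_tau2`, `omi_index`), morphology (`cell_area_um2`,
`nucleus_diameter_um`, `ncr`).

## Design / pipeline config (JSON)

`omi run --config` takes a document with top-level keys `seed`,
`demo_scenes`, `demo_image_shape`, `demo_cells`, `demo_cell_radius`,
`n_bins`, `bin_width_ps`, `irf_fwhm_ps`, `mean_photons_per_pixel`,
`omi_scale`, `alpha`, `overwrite`, and nested objects:

* `design` — the study: `samples`, `preparations` (subset of
  `fresh | flash_frozen | dmso_frozen`), `recovery_days`, `treatments`
  (must include the control arm), `timepoints_hr`, `organoids_per_group`,
  `cells_per_organoid`, `organoid_sd`, `seed`, `baseline` (endpoint means
  and SDs), and `effects`: a mapping from `"sample|preparation|treatment|hr"`
  to a three-vector of control-SD shifts on (redox ratio, NAD(P)H τ_m,
  FAD τ_m).  `prep_shifts` maps `"sample|preparation"` to a freezing shift
  applied to every arm of that preparation.
* `fit` — `photon_threshold`, `min_photons`, `max_bin_radius`, bounds and
  initializer overrides (see `omiflim.flim.FitConfig`).
* `segmentation` — see `omiflim.segmentation.SegmentationConfig`.

Unknown keys are rejected; validation (including the presence of the
control arm) runs before any computation, and every run writes its resolved
configuration to `config.resolved.json` next to its outputs.

See `examples/demo_config.json` for a complete working example.
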