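# Methods

## The decay model

Each pixel of a TCSPC image is a histogram of photon arrival times over one
laser period `T = n_bins × bin_width` (defaults: 256 bins of 48.8 ps, so
T = 12.5 ns, the period of an 80 MHz Ti:sapphire source).  The expected
curve is a two-component exponential

    I(t) = A [ α₁ e^(−t/τ₁) + α₂ e^(−t/τ₂) ] ⊛ IRF + C,  α₁ + α₂ = 1,

motivated by the free and protein-bound pools of NAD(P)H and FAD (free
NAD(P)H is the short component; for FAD the bound form is short).  The
amplitude-weighted mean lifetime is τ_m = α₁τ₁ + α₂τ₂.

Numerical conventions:

* all curves are sampled at bin centers; the IRF is convolved circularly
  over the period, so the IRF tail and the decay tail fold into the early
  bins as in a real high-repetition-rate measurement.  On the bin-center
  axis this discrete convolution reads out half a bin early — accounted for
  where absolute arrival times are measured (tests), irrelevant to fitting
  since simulator and fitter share the convention;
* incomplete decay ("wrap-around") is modeled from exactly one preceding
  pulse: each component carries a factor `1 + e^(−T/τ)`.  The residual error
  is O(e^(−2T/τ)), i.e. ~10⁻⁴ even at τ = 3 ns, far below shot noise;
* the IRF is a Gaussian of configurable FWHM (default 260 ps, the published
  instrument width), peaking at 10% of the window so pre-rise bins exist for
  background estimation.  Only the width is published; the Gaussian shape is
  a modeling choice.

## Simulation

`simulate_decay` scales the unit-sum convolved curve to a photon budget,
adds the flat background, and draws independent Poisson counts per bin.
Lifetimes beyond 5× the window set an ill-conditioned flag.  The default
budget of ~458 photons/pixel is the published acquisition scale
(5×10⁵ counts/s sustained over a 60 s, 256² frame); the per-pixel photon
count itself is not a published number.

Organoid scenes place non-overlapping disk cells (radius 8–13 px at
0.5 µm/px) with concentric elliptical nuclei rendered at 0.4× cytoplasm
intensity (NAD(P)H is extranuclear, so nuclei image dark; the contrast
value is the simulator's stated convention, giving the segmenter a defined
task).  Background pixels are flat in time (background light).  Photon
rates are relative until the whole scene is scaled — by one common factor,
so ground-truth redox ratios are preserved — to the target image mean.

Study designs (`generate_experiment`) draw per-cell endpoint tables
directly: redox ratio, NAD(P)H τ_m and FAD τ_m come from configurable
control baselines (defaults 1.0 ± 0.25, 0.9 ± 0.15 ns, 1.3 ± 0.2 ns,
within the range of published coenzyme values; the emulated study prints no
baselines).  Treatment and freezing effects are additive shifts in
control-SD units per (sample, preparation, treatment, timepoint).  Lifetime
components are drawn first (α₁, τ₁) and the long lifetime solved from the
drawn τ_m, so every record satisfies τ_m = α₁τ₁ + α₂τ₂ exactly.  Cells are
iid within a group by default, matching the downstream choice of the cell
as the experimental unit; `organoid_sd` adds an organoid-level random
intercept for sensitivity analyses.  Each group draws from a named
substream of the master seed, so adding arms never reshuffles existing
ones.

What the generator does *not* emulate: optical point-spread blurring,
detector afterpulsing and dead time, z-stacks, spatially varying
background, cell-shape irregularity, and organoid-level clustering (by
default).  Passing tests therefore demonstrate correctness of the
algorithms under the stated measurement model, not robustness to every
property of real acquisitions.

## Fitting

`fit_decay` minimizes a weighted least-squares objective over (α₁, τ₁, τ₂)
with the amplitude A and background C profiled out in closed form at every
step (variable projection); bounds are τ ∈ [0.05, 10] ns, α₁ ∈ [0, 1],
A, C ≥ 0.  Weights are Poisson-motivated: pass 1 uses 1/max(counts, 1),
pass 2 re-fits with 1/max(model, 1) from the first pass.  The second pass
removes the classic low-count bias of data-derived weights (median τ_m
error at 5×10³ photons drops from ~5% to ~3%); `reweight_passes=1` restores
the plain data-weighted fit.  A Poisson-MLE objective is not implemented;
the estimator is deliberately the weighted-least-squares family used by
standard TCSPC fitting software.

Initializers are channel presets (NAD(P)H: α₁ = 0.7, 0.3/2.0 ns; FAD:
0.3/2.2 ns); the initializer is canonicalized to τ₁ ≤ τ₂ first, which makes
the fit exactly invariant under relabeling of its starting point.  After
fitting, components are relabeled short-first and a τ₁ ≈ τ₂ tie (within
1 ps) collapses to a monoexponential (α₁ = 1), removing a non-identifiable
ridge.  C is initialized from the mean of the pre-rise bins.  The IRF–data
temporal shift is assumed zero (guaranteed by the simulator; real data
would need a shift parameter, a documented limitation).  Reported reduced
χ² uses the standard data-derived weights and n_bins − 5 degrees of
freedom.

Histograms with fewer than 100 background-subtracted photons are masked,
not fit.  Image fitting first bins each pixel with the smallest odd square
window (up to 7×7) reaching 300 summed counts — chosen so default simulated
cytoplasm needs radius ≤ 1 — and masks pixels that never reach it.  Masked
pixels carry NaN in every parameter map, never zeros.

`grid_fit_decay` is a brute-force reference: an exhaustive scan over
(α₁, τ₁, τ₂) at 0.01 / 0.02 ns resolution with closed-form A, C per node,
minimizing the same data-weighted objective.  It exists to certify the
iterative fitter's optimality (fit χ² ≤ 1.02× grid χ² on random instances)
and is far too slow for images.

## Segmentation

Foreground by Otsu threshold on a σ = 2 px Gaussian-smoothed image, holes
filled (nuclei are dim); nuclei as the dim Otsu class inside the foreground
eroded by 3 px (keeping the boundary roll-off out of the nucleus class),
minimum 12 px²; cells by watershed from the nucleus seeds on the
distance-from-nucleus elevation within the foreground, so touching cells
split midway between their nuclei (deterministic, unlike flooding on the
noisy intensity ridge); minimum cell size 30 px².  Morphology endpoints:
cell area (px × pixel_size²), nucleus diameter (region major-axis length ×
pixel_size, automating the longest-axis measurement), and NCR defined as
nucleus area / cytoplasm area (the CellProfiler convention for a
"nuclear-to-cytoplasm ratio"; nucleus/whole-cell is a config switch away).
One image is one organoid for the cells-per-organoid count.

## Endpoints and the OMI index

The redox ratio image is NAD(P)H intensity / FAD intensity per pixel, with
pixels below a 1-count FAD floor masked (the floor is a guard against
division blow-up, not a published value).  Per-cell endpoints average each
map over the cell's cytoplasm (the coenzymes are extranuclear; whole-cell
averaging is a config option) using only unmasked pixels.

The OMI index is z(redox) + z(NAD(P)H τ_m) − z(FAD τ_m) with each z
centered on the time-matched control group of the same sample, preparation
and recovery arm and, by default, scaled by that control group's SD;
center-only standardization is a config switch (the composite's published
definition fixes the coefficients (+1, +1, −1) but the scaling convention
is ambiguous).  Control-group mean OMI index is identically 0.

## Statistics

α = 0.05 throughout.  The experimental unit is the cell (n = 30–300 per
group), mirroring the emulated study; this understates organoid-level
variance if cells within an organoid are correlated — a deliberate,
documented caveat, since the point is to reproduce the study's ladder, and
the generator's default has no organoid clustering.

* Morphology / staining: Kruskal–Wallis, then Dunn's mean-rank z tests with
  tie correction, Bonferroni-adjusted over the performed pairs (Dunn's
  internal adjustment is implemented here directly; the Bonferroni choice
  is conservative and deterministic).
* Control FLIM endpoints: D'Agostino–Pearson omnibus normality (n ≥ 20
  enforced), then two-sided t tests with Bonferroni over the endpoint
  family (justified at n > 30 cells/group).
* Drug response: two-way ANOVA (treatment × time, Type II sums of squares
  for the unbalanced 30–300-cell groups), then Tukey–Kramer comparisons of
  each treatment against the time-matched control within each timepoint,
  computed directly from the studentized-range distribution (the k = 2 case
  reduces exactly to the two-sample t comparison).  A response call is
  decrease/increase when the Tukey-adjusted p < α with that sign, else
  none.  Tukey's HSD controls the familywise rate across all pairs at a
  timepoint, so with more than two groups the per-comparison type-I rate is
  intentionally below α; the null-calibration experiment therefore uses the
  minimal two-group design, where the nominal rate applies.
* Concordance: frozen-arm calls matched to fresh calls on (sample,
  treatment, timepoint); the comparison is three-level — a significant
  increase, a significant decrease and no change are mutually discordant
  (required: one preparation shows significant increases where another
  shows none).  Summaries per preparation and per recovery-day stratum.
* Fresh–frozen correlation: Spearman rank correlation of paired group OMI
  means (n ≥ 5 pairs).

## Validation problem sizes

The evaluation suite (`omiflim.evaluation`, driven by
`scripts/acceptance.py` and `tests/test_acceptance.py`) uses: 100 simulated
decays at 5×10³ photons for fit recovery and 20 instances for the grid
cross-check; 20 replicate two-group experiments of 1 000 cells each for
OMI-index normalization; 1 000 null replicates per calibrated test; one
full 2-sample × 3-preparation × 4-drug × 3-timepoint study at 180
cells/group for end-to-end call recovery; and 50 random scenes of 5–50
cells for segmentation.  These sizes keep each experiment in the seconds-
to-minutes range while leaving Monte-Carlo error well inside the asserted
tolerances.

## Known limitations

* No vendor (.sdt) file reader; the documented HDF5 layout is the exchange
  format, and a vendor adapter would be a straightforward addition.
* No IRF–data shift fitting, no multi-component (>2) or global fitting, no
  phasor analysis.
* The pipeline's image stages run on demo scenes per run; fitting every
  pixel of a full multi-arm study (hundreds of 256² cubes) is out of scope
  for a single pipeline invocation, matching practice where per-image
  fitting is a separate interactive step.
* Published per-preparation discordance marginals cannot all be
  reconstructed from the running text of the emulated study; only the
  aggregate 7-day / 72-hr cell (4/24) is asserted.
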