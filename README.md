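# omiflim

Optical metabolic imaging (OMI) of tumor organoids, as a tested Python
pipeline: simulation of two-channel NAD(P)H / FAD time-correlated
single-photon-counting (TCSPC) image data, per-pixel fluorescence-lifetime
fitting with instrument-response deconvolution, cell segmentation, per-cell
metabolic endpoints, and the drug-response statistics down to fresh-vs-frozen
concordance scoring.

## The problem

Primary tumor organoids report early drug response through shifts in the
autofluorescence of the metabolic coenzymes NAD(P)H and FAD.  Fluorescence
lifetime imaging resolves each coenzyme's free and protein-bound pools,
whose decays are modeled per pixel as

```
I(t) = A [ α₁ e^(−t/τ₁) + α₂ e^(−t/τ₂) ] ⊛ IRF + C ,   α₁ + α₂ = 1
```

with the short component first (τ₁ ≤ τ₂), `C` a flat background, and ⊛
convolution with the measured instrument response over one laser period.
The amplitude-weighted mean lifetime is `τ_m = α₁τ₁ + α₂τ₂`.  Per cell,
three endpoints — the optical redox ratio (NAD(P)H intensity / FAD
intensity), NAD(P)H τ_m and FAD τ_m — are standardized against the
time-matched control group and combined into the OMI index,

```
OMI index = z(redox) + z(NAD(P)H τ_m) − z(FAD τ_m) ,
```

whose significant decrease versus control marks drug response.  Comparing
per-(treatment, timepoint) response calls between organoids grown from
fresh and from frozen tissue gives a concordance table: the evidence for
whether banked, frozen tumor tissue can replace fresh tissue in
organoid drug testing.

No public raw data exist for this assay, so the package ships a first-class
synthetic-data module that generates ground-truthed photon cubes, organoid
scenes and full multi-arm studies at the published acquisition scale
(256×256 pixels, 12.5 ns window in 256 bins, 260 ps FWHM Gaussian IRF,
~458 photons/pixel, 6 organoids and 30–300 cells per group); every
downstream stage is tested against that ground truth.

## Worked example

```python
from omiflim import synthetic as syn, flim
from omiflim.types import DecayParams
from omiflim.reference import reference_calls_72hr
from omiflim.stats import concordance

# fit a simulated NAD(P)H decay
irf = syn.make_irf()                      # 260 ps FWHM, 256 x 48.8 ps bins
truth = DecayParams.make(alpha1=0.75, tau1=0.4, tau2=2.6)
sim = syn.simulate_decay(truth, irf, photon_budget=5e3, seed=1)
fit = flim.fit_decay(sim.counts, irf)
print(f"true tau_m = {flim.mean_lifetime(truth):.3f} ns, "
      f"fitted tau_m = {fit.tau_m:.3f} ns "
      f"(alpha1 = {fit.params.alpha1:.2f}, chi2_r = {fit.chi2_reduced:.2f})")

# score the published 72-hr response calls, frozen vs fresh preparations
fresh, frozen = reference_calls_72hr()
conc = concordance(fresh, frozen)
print(f"discordant calls: {conc.n_discordant}/{conc.n_total} "
      f"({100 * conc.inconsistency_fraction:.0f}%)")
```

prints

```
true tau_m = 0.950 ns, fitted tau_m = 0.975 ns (alpha1 = 0.77, chi2_r = 1.06)
discordant calls: 4/24 (17%)
```

The first line is a 5 000-photon decay recovered within fit tolerance of
its ground truth; the second scores the six published 7-day frozen-tissue
preparations against their fresh counterparts at 72 h of drug treatment —
4 of 24 treatment-level calls disagree (the flash-frozen preparations miss
one paclitaxel response, two significant OMI increases, and one combination
response; the DMSO-frozen calls all match).

A full pipeline run (simulate → fit → segment → endpoints → stats) is one
command:

```
omi run --config examples/demo_config.json --out results_demo --seed 1
```

producing `cells.csv` (per-cell endpoints + OMI index), `calls.csv`
(response calls), `concordance.csv` and a Markdown report.  See
`docs/file_formats.md` for the HDF5 cube layout and the design/config JSON
schema, and `docs/methods.md` for the model, parameter and design notes.

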