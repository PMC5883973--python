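# calfnmr

Synthetic ¹H-NMR plasma metabolomics pipeline for neonatal calf sepsis.

Sepsis is a leading cause of death in newborn dairy calves, and its early
signs are clinically nonspecific. NMR metabolomics of plasma can separate
septic from healthy animals within one measurement: a longitudinal study
design with 10 healthy calves (Ha) and 20 severely septic calves sampled at
0, 3, 6, 24, 48 and 72 h after admission (113 spectra), three 1D experiments
per sample (NOESY-, CPMG- and diffusion-edited-type), OPLS-DA classification
under Monte Carlo cross-validation, and absolute quantification of 22
metabolites by qNMR. The raw spectra of such studies are rarely deposited,
so `calfnmr` makes the whole workflow reproducible on synthetic data: it
generates spectra from the published per-group concentration table
(mean ± SD, μM) and runs the full analysis chain on them.

The package is aimed at metabolomics methodologists and veterinary
researchers who want a tested, end-to-end reference implementation of this
workflow — simulation, processing, chemometrics, quantification and
statistics — whose every stage is checked against ground truth.

## The core methods

* **Study synthesis** — per-sample concentrations are lognormal draws
  moment-matched to the published group moments:
  σ² = ln(1 + SD²/mean²), μ = ln(mean) − σ²/2. A rule classifier implements
  the SIRS → sepsis → severe-sepsis criteria on vital signs.
* **Spectrum simulation** — sums of decaying complex exponentials at
  600.13 MHz (FWHM = r₂/π Hz), J-split multiplets, TMSP and 1,4-dioxane
  references, residual water, broad macromolecule background, shift jitter
  and complex Gaussian noise; pulse sequences are reduced to per-component
  relaxation/diffusion weights (CPMG suppresses macromolecules,
  diffusion-editing suppresses small molecules).
* **Processing** — 0.3 Hz exponential apodization + FT, automatic phase
  (negative-intensity minimization) and asymmetric-least-squares baseline
  correction, calibration to the anomeric glucose doublet at 5.24 ppm, and
  0.02 ppm binning over 0.2–10 ppm with water exclusion (490 → 465 bins).
* **Chemometrics** — PCA and OPLS-DA written from first principles: the
  response-orthogonal variation is filtered out (orthogonal scores satisfy
  tᵀY = 0 to machine precision; with zero orthogonal components the model
  is exactly PLS2), 10 total components, and a 100-cycle stratified 90/10
  Monte Carlo cross-validation accumulating a 7-class confusion matrix.
  Bin features pass through a generalized-log variance stabilization before
  centering.
* **qNMR** — each metabolite's designated signal is fitted as a Lorentzian
  cluster (shared linewidth pinned on the dioxane standard) and converted to
  plasma-scale μM via conc = (A_met/n_met)/(A_diox/8) · C_diox · dilution.
* **Statistics** — tie-corrected Kruskal–Wallis across the 7 groups, Dunn
  post hoc z-tests on all 21 pairs, Benjamini–Hochberg FDR (significant:
  adjusted p < 0.05), and hypergeometric pathway over-representation against
  five packaged pathway sets.

## Worked example

Simulate one healthy sample, process its CPMG-analogue spectrum, and
quantify it against the internal standard:

```python
from calfnmr import (load_library, AcquisitionParams, synthesize_fid,
                     process_fid, quantify_metabolites)
from calfnmr.synthesis import generate_manifest, sample_concentrations

library = load_library()                      # 22 metabolites, Table-style moments
manifest = generate_manifest({"Ha": 1}, seed=0)
true = sample_concentrations(manifest, library, seed=0)
print("true creatine (uM):", round(true.loc["Ha-01", "Creatine"], 1))

fid = synthesize_fid(true.loc["Ha-01"].to_dict(), library,
                     AcquisitionParams(experiment="cpmg"), seed=0)
spectrum = process_fid(fid)                   # apodize+FT, phase, baseline, calibrate
conc = quantify_metabolites(spectrum, library)
print("qNMR creatine (uM):", round(conc["Creatine"], 1))
print("qNMR allantoin (uM):", round(conc["Allantoin"], 1))
```

Output:

```
true creatine (uM): 90.5
qNMR creatine (uM): 90.5
qNMR allantoin (uM): 57.6
```

The drawn healthy creatine concentration (90.5 μM, from the healthy
distribution 168.8 ± 74.5 μM) is recovered exactly by the dioxane-ratio
quantification; allantoin sits at a typical healthy level, an order of
magnitude below the septic admission mean (501.4 μM).

The full pipeline — simulate, process all three experiments, cross-validate
the classifier, quantify, test group differences, and run pathway
enrichment — is one call (or `calfnmr run-all --out rundir` on the command
line):

```python
from calfnmr import PipelineConfig, run_pipeline
run_pipeline(PipelineConfig(seed=101), "rundir")
```

which writes the manifest, binned matrices, MCCV confusion-matrix reports,
the 22-column qNMR concentration table, the Kruskal–Wallis/Dunn/BH tables
and the pathway enrichment results, each stamped with the configuration
hash.

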