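# Methods

`calfnmr` replicates, on synthetic data, the analysis workflow of a
longitudinal ¹H-NMR plasma metabolomics study of severe sepsis in newborn
dairy calves: 10 healthy controls (Ha) and 20 diseased animals sampled at
0, 3, 6, 24, 48 and 72 hours after admission. The raw spectra of the original
study are not public, so the package generates its own spectra from the
published per-group concentration table and runs the full downstream
analysis on them. This note records the models, the defaults and the design
choices, and what the synthetic setting does and does not demonstrate.

## Study synthesis

The default manifest holds 113 acquired samples
(Ha 10, 0 h 20, 3 h 20, 6 h 20, 24 h 17, 48 h 14, 72 h 12); one 0 h sample
is flagged `removed` for bad spectral quality, so analyses see n = 19 at 0 h.
Animal deaths over time are encoded purely through the shrinking group sizes,
not as an explicit survival process. Time points are treated as independent
groups throughout, mirroring the published statistics.

Per-sample metabolite concentrations are independent lognormal draws
moment-matched to the published group mean and SD (μM):
σ² = ln(1 + SD²/mean²), μ = ln(mean) − σ²/2. The lognormal guarantees
positivity and the right skew for plasma metabolites, and mean/SD are the
only published moments; SD = 0 degenerates to a point mass. Concentrations
are independent across metabolites because no covariance was published — an
important idealization: real metabolite panels are correlated, which would,
if anything, make multivariate class separation easier.

The SIRS/sepsis rule classifier counts four criteria (temperature > 39 °C or
< 36 °C; heart rate < 100 or > 160 bpm; respiratory rate > 65/min or
pCO₂ > 50 mmHg; leukocytes > 12 000/mm³ or < 4 000/mm³ or band neutrophils
> 10 %): ≥ 1 criterion → SIRS; ≥ 2 with infection → sepsis; all 4 with
infection and ≥ 1 organ failure → severe sepsis. The classifier is monotone
in the satisfied criteria.

## Spectrum simulation

Each sample is rendered as a sum of decaying complex exponentials at
600.13 MHz: a line with amplitude *a*, frequency *f* and relaxation rate
*r₂* (s⁻¹) contributes *a*·exp((2πi f − r₂)t); its absorption Lorentzian has
FWHM = r₂/π Hz. Amplitudes are (plasma concentration / dilution factor) ×
proton count; the dilution factor is 2.0 (equal-volume plasma + buffer
mixing). Multiplets are J-split stick patterns (doublet 1:1, triplet 1:2:1,
quartet 1:3:3:1; "multiplet" an idealized 4-line cluster); strong-coupling
and pH-shift effects are out of scope.

The three acquired experiments are modeled as per-component weights, not
pulse-sequence physics: `noesy` weight 1 for everything; `cpmg`
weight exp(−r₂·t_cpmg) with t_cpmg = 0.1 s (macromolecules, r₂ = 60 s⁻¹,
suppressed to 0.25 %; small metabolites, r₂ = 3 s⁻¹, uniformly attenuated
to 74 % so internal-standard ratios stay unbiased); `diffedit` weight equal
to each resonance's diffusion coefficient (0.05 for small molecules, 0.9
for macromolecules, 0.01 for water).

Defaults: 2¹⁵ complex points over a 14 ppm window centered at 5 ppm
(covers −2 to 12 ppm); TMSP at 0.00 ppm and 1,4-dioxane at 3.70 ppm
(100 μM in-tube) as reference compounds; residual water as one broad line
at 4.70 ppm (100× metabolite linewidth); a seven-line broad macromolecule
background whose per-sample level is lognormal with CV 0.2. Additive
complex Gaussian noise with SD 24 (FID units) puts the median quantification
signal-to-noise ratio across the 22 metabolites at healthy concentrations
at ≈ 50. Two jitter scales emulate calibration error: a per-sample global
shift (SD 0.005 ppm, correctable by calibration) and a per-resonance shift
(SD 0.001 ppm, not correctable — the motivation for binning).

Per-sample random effects (global shift, peak jitter, macromolecule level)
are shared across the three experiments of a sample, modeling one tube
measured three times; the noise differs per acquisition. Everything is
reproducible from one seed via derived substreams.

## Spectral processing

FIDs are multiplied by exp(−π·0.3·t) (0.3 Hz Lorentzian line broadening,
which adds exactly 0.3 Hz to each FWHM), first point halved, Fourier
transformed and scaled by the dwell time (continuous-FT approximation; with
this convention a line of amplitude *a* integrates to *a*/2 over the
frequency axis — immaterial downstream because all consumers use ratios or
per-sample patterns).

Phase correction minimizes the summed magnitude of negative intensities over
0.2–10 ppm in (φ₀, φ₁), coarse φ₀ grid then Nelder–Mead; it recovers
injected zero-order errors to well under 1°. Baseline correction is
asymmetric least squares (λ = 10⁷, p = 0.001, banded solver); at these
defaults it removes offsets and ramps essentially exactly and costs ~1 % of
narrow-peak integrals, identically for analyte and standard. The ppm axis is
calibrated by locating the anomeric glucose doublet near 5.24 ppm (two
dominant find-peaks maxima, J-split separation 0.002–0.03 ppm, required to
stand 8 robust SDs above the local noise floor so an anchor-free window is
never mistaken for a doublet) and translating the axis; a TMSP (0 ppm)
fallback is available but off by default.

Binning integrates the intensity over left-closed 0.02 ppm bins tiling
0.2–10.0 ppm (490 bins); integrals are exact trapezoids obtained by
augmenting the grid with the bin edges, so binning is exactly additive. Bins
overlapping the water exclusion window (default 4.50–5.00 ppm, configurable,
kept clear of the 5.24 anchor) are dropped, leaving 465 features. No
between-sample normalization is applied.

## Chemometrics

OPLS-DA: classes are dummy-coded (one centered indicator column per class).
Orthogonal components use the loading-filtering step: the loading of a
provisional one-component PLS direction is orthogonalized against the full
column space of XᵀY and deflated from X; this makes every orthogonal score
exactly response-orthogonal (tᵀY = 0 to machine precision) and leaves XᵀY
invariant, after which a NIPALS-style PLS2 with `n_pred` components is
fitted on the filtered matrix (weights computed as dominant singular vectors
of XᵀY — the NIPALS fixed point — with a deterministic sign). With
`n_orth = 0` the model is exactly PLS2. Prediction removes the training
orthogonal components from new samples, applies the regression coefficients
W(PᵀW)⁻¹Qᵀ, and assigns the argmax class with a first-in-order tie-break.

Ten total components are retained, split `n_pred` = 6 (classes − 1) and
`n_orth` = 4 by default; both are configurable. Monte Carlo cross-validation
runs 100 stratified random 90/10 splits (stratification is necessary: with
10 healthy samples an unstratified 10 % draw would often contain none),
accumulating one confusion matrix; per-class accuracy is that class's
sensitivity in the accumulated matrix, and "mean accuracy" the overall
fraction correct. Iteration *i* draws from substream *i* of the seed.

Feature transform: bin integrals inherit the lognormal skew of the
concentrations, and linear projections on such heavy-tailed features are
dominated by the high-variance glucose region — OPLS-DA on raw centered
bins plateaus near 80 % healthy-class sensitivity on this generator
(independent linear classifiers plateau similarly), below the
90–100 % the original study reports on real spectra. The default is
therefore the generalized log transform glog(x) = ln((x + √(x² + λ))/2)
with λ = 10⁻⁶ (well below typical peak-bin integrals; results are
insensitive to λ over 10⁻⁸–10⁻⁴), a standard variance stabilization in
NMR metabolomics that is monotone and defined for the small negative values
noise leaves in empty bins. Columns are then mean-centered only — no
unit-variance or Pareto scaling. `feature_transform: none` restores plain
centering.

PCA is a thin SVD of the centered matrix with deterministic loading signs,
verified against a covariance eigendecomposition oracle.

## qNMR quantification

Each metabolite has one designated quantification signal, chosen (positions
and multiplicities are packaged from public reference values, not from the
study, which did not print its assignment table) so that every ±0.04 ppm fit
window is free of other library lines; windows are fitted as J-split
Lorentzian clusters with a free bounded center shift and a local linear
baseline. Library signals whose lines fall within 0.02 ppm of a window are
fitted jointly as additional components (this joint path also covers user
override libraries with genuine overlap). The area is the analytic integral
π·height·γ of the fitted cluster — insensitive to window truncation. If the
residual RMSE exceeds max(0.15 × height, 3 × noise floor) the method falls
back to direct trapezoidal integration and records it.

The linewidth is measured once per spectrum on the high-SNR dioxane standard
and then pinned (r₂-corrected) for the metabolite fits: freeing the
linewidth roughly doubles weak-signal area variance through the
height/width anticorrelation. Concentrations follow
conc = (A_met/n_met)/(A_diox/8) · C_diox · dilution, with C_diox the in-tube
standard concentration (default 100 μM — the real value was not published;
only the ratio matters) and dilution 2.0 restoring plasma scale. The ratio
form makes quantification invariant to global intensity scaling.
Quantification uses CPMG-analogue spectra, where the relaxation filter is
uniform across the small-molecule class by construction, so ratios are
unbiased — a simulator-level simplification documented here; with real
spectra, differential relaxation would bias CPMG-based qNMR.

Two quantification signals deviate from the most literature-typical choice
for precision reasons: proline is integrated at its 3-proton 1.99 ppm
multiplet and glycerophosphocholine at a 2-proton 3.61 ppm multiplet,
because single-proton signals of 30–100 μM metabolites at the default noise
level are too imprecise for reliable per-sample quantification.

## Group statistics and pathway enrichment

Per metabolite: tie-corrected Kruskal–Wallis H across the seven groups
(χ², 6 df; all-identical input returns p = 1), Dunn's pairwise z on pooled
mean ranks with tie-corrected variance over all 21 group pairs, and
Benjamini–Hochberg step-up adjustment. The BH family is the 21 pairs within
one metabolite (the publication did not state the family); a global family
over all 22 × 21 tests is available behind a flag. Significance is adjusted
p < 0.05; both raw and adjusted p are reported.

Pathway over-representation is a minimal hypergeometric upper tail
P(X ≥ hits) of the significant set against each of the five packaged pathway
sets (aminoacyl-tRNA biosynthesis; valine/leucine/isoleucine biosynthesis;
nitrogen metabolism; glycine/serine/threonine metabolism; ketone-body
synthesis and degradation), with member names resolved through a synonym
map. The background is the 22 quantified metabolites, not a full compound
database, and no topology or impact scoring is attempted — this is a
declared minimal substitute for full pathway-analysis software, adequate
because the pathway list is used qualitatively.

## Problem sizes and numerical choices

Default runs use 2¹⁵-point FIDs, the 113-sample study, 100 MCCV cycles;
the acceptance script additionally quantifies 500 healthy spectra and draws
500 generator samples, all single-threaded in a few minutes. Tests exercise
the same operations at the same acquisition defaults, with smoke-scale runs
(2 groups, 2¹³–2¹⁴ points, 5 CV cycles) for pipeline plumbing. Tie-breaks
and sign conventions are deterministic everywhere (argmax takes the first
class in sorted order; SVD signs fixed by the largest-magnitude element).
Degenerate inputs are defined: all-identical statistics return p = 1, empty
manifests yield empty outputs, sd = 0 distributions are point masses.

## What passing tests do and do not show

The generator reproduces the published group moments, realistic lineshapes,
references, background, water and shift jitter — so passing tests show the
*pipeline* is correct and self-consistent: processing recovers known
truths, the classifier separates what is separable, quantification is
accurate and linear against ground truth. They do not validate the
biology: concentrations are independent lognormals with no animal-level
correlation structure, no repeated-measures dependence between time points
of the same animal, no pH- or protein-binding shift variation, no
differential relaxation, and macromolecule lineshapes are a modeling
choice. Healthy-class separability in particular is driven entirely by the
published mean/SD differences (creatine, allantoin, phosphocreatine +
creatinine, isobutyrate, choline are the dominant markers), which this
generator makes cleanly attainable; the original study's 90/100 % healthy
accuracy on real spectra reflects additional structure this simulation does
not model.
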