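# Methods

`sialospec` re-implements, as a tested and reusable pipeline, an
uncertainty-aware workflow for classifying saliva ATR-FTIR spectra of
Sjögren's disease patients versus healthy controls. Because no clinical
cohort ships with the package, every stage is exercised against a synthetic
cohort generator that reproduces the statistical structure the workflow
assumes. This note records the models, the defaults and why they were
chosen, what the generator does and does not emulate, and the numerical
choices that matter.

## Data model

A cohort is a `SpectrumSet`: a strictly ascending wavenumber grid (cm⁻¹),
an `n_spectra × n_wavenumbers` absorbance matrix, and per-spectrum links to
donors. The donor — not the spectrum — is the unit of cross-validation and
of the final diagnostic call, because replicate spectra from one saliva
stain are strongly correlated. Files use a plain two-CSV dialect (matrix +
metadata); instrument-convention descending grids (4000 → 650 cm⁻¹) are
flipped on read. The default synthetic grid covers 650–3700 cm⁻¹ at
2 cm⁻¹ spacing (1526 points). The instrument resolution in the emulated
acquisition protocol is 4 cm⁻¹, but the digitized data interval of such
exports is typically finer and is configurable here; 2 cm⁻¹ is the package
default.

## Synthetic cohort generator

Each spectrum is built as

    scatter · ( Σᵢ aᵢ (1 + uᵢ) Gᵢ(ν) + s(ν)·[disease, non-ambiguous] )
    + polynomial baseline + white noise

* `Gᵢ` are Gaussian absorption bands at the canonical saliva positions
  (Amide I 1636, Amide II 1549, CH₃ 1447, COO⁻ 1398, PO₂⁻ 1342, the
  Amide III/carbohydrate envelope at 1072, a low-wavenumber band at 880 and
  the broad OH/Amide A envelope at 3290 cm⁻¹).
* `uᵢ ~ N(0, donor_sd²)` are donor-level random amplitude effects shared by
  all of a donor's spectra. They induce the within-donor correlation that
  makes patient-level cross-validation measurably different from
  spectrum-level splitting.
* `s(ν)` is the class-shift profile: a smooth plateau equal to the
  configured delta inside each disease zone, tapered over 25 cm⁻¹.
* Scatter is multiplicative (`1 + N(0, scatter_sd²)`, clipped positive),
  the baseline is a random degree-6 Legendre polynomial, and the white
  noise is i.i.d. Gaussian. The baseline degree deliberately matches the
  degree the EMSC step removes, so preprocessing is exactly matched to the
  corruption model; set `baseline_degree` differently to study mismatch.
* **Ambiguity**: with probability ρ (`ambiguity_fraction`), independently
  per spectrum of each diseased donor, the class shift is omitted and the
  spectrum is drawn exactly from the control distribution. This models
  stain locations that contain no biomarker. Ground truth ids are returned
  for parameter-recovery studies.

Defaults: 23 control + 24 disease donors, 5 spectra per donor (235
spectra), all female, ρ = 0.4, `donor_sd` 0.08, `scatter_sd` 0.05,
`noise_sd` 0.005, `baseline_scale` 0.05, disease deltas +0.02 in
956–1210 cm⁻¹ and −0.015 in 1579–1800 cm⁻¹ (absorbance units, against band
amplitudes of order 0.3–1.0).

The effect sizes were calibrated once, before the test suite was frozen, to
place the single-phase classifier in the moderate-performance regime
(spectral accuracy in the low–to–mid 0.7s, donor accuracy around 0.8) where
training-set refinement has room to act. Two properties of the calibrated
regime matter and are worth stating explicitly:

1. Class overlap is comparable to the donor-level variability, so the 40%
   of disease-labeled training spectra that are actually control-like pull
   the phase-1 decision boundary into the informative cluster; removing
   them measurably improves the phase-2 classifier.
2. Per-spectrum distortion (scatter, noise) is small relative to the shared
   donor effect. This matters because ambiguous test spectra are
   *exchangeable with controls by construction*: a sloppy classifier that
   calls borderline control-like spectra "disease" at some rate q collects
   accidental majority-vote wins on ambiguous-heavy disease donors while
   losing control donors. When per-spectrum jitter is large, that rescue
   channel can fully mask the benefit of refinement at the donor level even
   though the refined model is strictly better at the spectrum level. With
   the calibrated defaults the paired 10-seed comparison shows both the
   spectral gain (≈ +4 points) and a positive donor-level gain.

What the generator does **not** emulate: ATR penetration-depth physics,
water-vapor and CO₂ bands, Mie scattering, Lorentzian/Voigt line shapes,
instrument drift between sessions, or male donors (sex metadata exists but
defaults to an all-female cohort, mirroring the sex-restricted modeling
protocol the pipeline targets). Passing tests therefore demonstrate the
*workflow's* correctness and its behavior under the assumed statistical
structure — not clinical performance on real saliva spectra.

## EMSC preprocessing

Model-based extended multiplicative signal correction decomposes each raw
spectrum by least squares as `raw ≈ b·reference + Σₖ pₖ Pₖ(x)` where `Pₖ`
are Legendre polynomials (degree ≤ 6 by default) on the wavenumber axis
mapped affinely to [−1, 1]. The corrected spectrum is
`(raw − Σ pₖPₖ)/b`. Choices:

* **Orthogonal basis.** Raw powers of a 3050 cm⁻¹ axis at degree 6 are
  catastrophically conditioned; the Legendre design keeps the condition
  number small (asserted in tests against the raw-power design).
* **Reference = training-fold mean**, recomputed inside every CV fold. The
  reference is a fitted quantity; sharing it across folds would leak test
  information through preprocessing.
* **Degenerate fits**: |b| < 1e−6 raises with the spectrum id rather than
  silently dividing.
* **Cropping to 650–3700 cm⁻¹ happens after correction**, matching the
  acquisition-then-preprocess ordering the pipeline emulates; cropping is a
  closed interval.

On spectra constructed exactly as `b·reference + degree-6 polynomial` the
correction recovers the reference to < 1e−8 relative error (500-spectrum
check in the acceptance suite), and re-correcting with the same model is an
exact fixed point. Re-correcting with a *recomputed* reference moves
spectra by well under 1% of the first-pass correction at the default noise
levels; exact idempotence under reference recomputation is not a property
of EMSC and is not claimed.

## PCA-LDA baseline

PCA (scikit-learn, full SVD) is fit on training-fold spectra only; the
number of retained components is the smallest k whose cumulative explained
variance reaches the target (default 0.99, capped at the centered rank).
The discriminant is the two-class Fisher closed form
`w ∝ S_w⁻¹(μ_disease − μ_control)` with a midpoint threshold (equal
priors — the cohort is nearly balanced and the intended use is screening).
A singular within-class scatter is ridge-regularized with
`ε = 1e−6·trace(S_w)/dims`. Scores exactly at the threshold are called
control: a deterministic, conservative tie-break for a positive-screen
label.

## Windowed spectral network

The classifier is a small dense network specialized for 1-D spectra: the
input is cut into overlapping windows (default 50 grid points, stride 25;
a tail window anchored at `n − w` guarantees full coverage), each window
feeds its own tanh dense block (8 units), the blocks are concatenated into
a tanh head (16 units) carrying Bernoulli dropout (p = 0.3), and a single
sigmoid unit emits the disease probability. It is implemented directly in
numpy with manual backpropagation and Adam (lr 1e−3, batch 32), trained
for exactly 200 epochs with no early stopping; weights, batch order and
dropout masks all derive from one seed, so training is bit-reproducible
single-threaded.

Dropout uses the classic formulation: training and stochastic inference
multiply head activations by a raw Bernoulli(1−p) mask; deterministic
inference scales activations by (1−p). The mean over stochastic passes
therefore converges to the deterministic output, which is what makes the
Monte Carlo estimate below enumerable on toy models.

The loss is binary cross-entropy with inverse-prevalence class weights
(`balanced_loss`, on by default). The refinement stage deliberately
produces an imbalanced training set (all controls, at most ~40% of disease
spectra); unweighted BCE would shift the phase-2 operating point away from
the fixed 0.5 decision cut used at evaluation, conflating selection with
threshold movement. Weighting keeps the two phases comparable at the same
cut. Set `balanced_loss=False` for the unweighted loss.

Window size, stride and unit counts are configurable; the defaults were
chosen for a ~30k-parameter model that trains in seconds on a 235-spectrum
cohort.

## Monte Carlo Dropout

With dropout kept active, T stochastic forward passes (default T = 100)
give per-spectrum moments

    ŷ = (1/T) Σₜ f⁽ᵗ⁾(x),    Var(y) = (1/T) Σₜ f⁽ᵗ⁾(x)² − ŷ²

The population (biased) form is used, evaluated as the mean squared
deviation from ŷ so that an all-identical pass set (p = 0) yields exactly
zero; any residual negative rounding is clipped to zero and counted. The
uncertainty score is Var(y) itself — not predictive entropy or |ŷ − 0.5|.
T = 100 keeps the standard error of the variance estimate around 10% of
its value at negligible cost. A closed-form reference model
(`LinearDropoutNet`, a single linear unit with input dropout whose moments
are exhaustively enumerable over all 2^d masks) validates the estimator to
three standard errors in the acceptance suite.

## Two-phase refinement

Per training fold: (1) train on all training spectra; (2) score MCD
variance for every *training* spectrum; (3) keep all control spectra and,
per disease donor, the lowest-variance spectra — by default the lowest 40%
(`keep_fraction`), never fewer than `max(1, ⌈0.20·n⌉)` (`retention_floor`);
(4) re-initialize from fresh random weights (a fixed seed offset, never a
warm start — retained weights tend to stay in the minimum shaped by the
noisy phase-1 set) and retrain on the refined set for the full epoch
budget. A variance-threshold rule (`below_threshold`) is also provided;
the fractional rule is the reproducible default since it does not depend
on the scale of Var(y). Test folds are never masked: every test spectrum
is predicted, and donors are called by strict majority vote over their
spectrum-level calls (probability > 0.5; an exact tie goes to disease —
screening favors sensitivity; with an odd number of spectra per donor ties
do not occur).

## Evaluation protocol

Donor-level stratified K-fold cross-validation (default K = 7): donors are
shuffled per class by seed and dealt round-robin with a fold counter
carried across classes, so fold sizes differ by at most one donor and class
proportions per fold by at most one donor. All of a donor's spectra share
its fold. Per fold, the EMSC reference, PCA-LDA, networks and selection
mask are fitted on training donors only; this is enforced by a taint test
that perturbs each test fold and asserts the fitted models' byte digests
are unchanged. Metrics are pooled over folds (micro-averaged): accuracy,
disease-class sensitivity (TPR) and mean sensitivity (the unweighted mean
of the two class sensitivities, i.e. balanced accuracy) at both the
spectrum and donor level, plus per-fold breakdowns and confusion counts.

## Zone-level Shapley attribution

Spectra are summarized by mean intensity over contiguous fingerprint zones.
The coarse scheme has 8 zones with edges {650, 825, 956, 1210, 1312, 1372,
1477, 1579, 1800} cm⁻¹ (the 1372–1477 interval is its own zone so the
scheme tiles the range); the fine scheme splits 956–1210 into A (956–1030),
B (1030–1170) and 1170–1210. The network is explained through a surrogate:
a zone-feature row is painted back into a full spectrum (each zone mean
broadcast across its zone; grid points above 1800 cm⁻¹ are held at the
cohort mean spectrum and never attributed) and passed to the trained
network. Shapley values are computed against a background set — the
training-fold control spectra, so attributions answer "what pushes this
spectrum toward disease relative to controls". For ≤ 12 zones all 2^M
coalitions are enumerated, so local accuracy (Σφ = f(x) − baseline), the
dummy axiom and the symmetry axiom hold to machine precision and the
linear-model closed form `φᵢ = wᵢ(xᵢ − mean background)` is matched to
1e−10; larger schemes fall back to sampled feature permutations. Global
summaries rank zones by mean |φ| and emit the per-point (φ, normalized zone
intensity) scatter table behind a beeswarm-style summary plot.

## Problem sizes and determinism

The acceptance script and the heavy acceptance tests use: 500 spectra for
the EMSC oracle; T = 10,000 passes for the MCD enumeration check; 1,000
randomized report sets for the selection invariants; one default cohort
with a reduced network (12 epochs) for the leakage taint test; ten default
cohorts with the full default network (200 epochs, T = 100) for the
refinement comparison; and ten 12-donor cohorts (60 epochs) for Shapley
localization. These sizes make the full suite a desk-scale run while
keeping every stochastic margin comfortably away from its threshold. All
randomness flows through explicit integer seeds; repeated runs are
bit-identical in single-threaded execution.

## Known limitations

* The refinement benefit is demonstrated on synthetic cohorts whose
  ambiguity mechanism is exactly the one the selection strategy assumes;
  real label noise need not follow it.
* The donor-level gain from refinement is structurally small at ρ = 0.4
  (see the calibration discussion above); the unambiguous gains are at the
  spectrum level and in control specificity.
* The surrogate used for zone attribution (zone means broadcast into flat
  zone profiles) evaluates the network off the manifold of realistic
  spectra; attributions describe the surrogate's view of the model.
* No vendor file formats, resampling between grids, atmospheric
  compensation, or GPU training.
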