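# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `spectrograin`, in the spirit of a chemometric methods
section.

## Data model

The pipeline's universal container is the `SpectrumSet`: an
`(n_samples, n_bands)` unitless reflectance matrix, a strictly ascending
wavelength grid in nanometres, one class label and one unique sample id per
row. Reflectance against a gray reference panel is computed per band as
`R = DN / DN_panel * R_panel` (digital numbers of sample and panel, known
panel reflectance); a seed's spectrum is the mean DN over the largest
4-connected pixel component above a brightness threshold at a chosen band
(default 685 nm, where seed/background contrast is high), optionally averaged
over front and back sides of the seed. Dark-current subtraction is assumed to
have happened upstream, but a per-band dark vector can be supplied and is
then subtracted from both sample and panel DN before conversion.

## Synthetic generator

The generator emulates, at the per-seed mean-spectrum level, the statistical
structure the analysis assumes:

* **Base curve** — a logistic red edge (centred 705 nm, width 45 nm) from a
  0.12 visible floor to a ~0.50 NIR plateau, plus Gaussian features giving a
  local maximum near 638 nm, a chlorophyll-absorption minimum near 675 nm
  and a shoulder maximum near 702 nm. Amplitudes (0.055–0.085 reflectance)
  are design constants chosen to keep spectra in a realistic 0.10–0.55
  range; on the default 128-band grid the realised extrema fall at 639, 674
  and 702 nm (within one 5.3 nm band of the nominal positions).
* **Class structure** — each variety adds smooth Gaussian bumps
  (σ = 15 nm by default) confined by a hard window mask to 638–660 nm and
  700–980 nm, the regions where varieties genuinely differ. Bump amplitudes
  are `N(0, 0.02) * class_separation`. The mask makes between-class variance
  *exactly* zero outside the windows, which is what makes wavelength
  selection a well-posed recovery problem. For selector validation the bumps
  can instead be planted at explicit wavelengths
  (`class_bump_centers_nm`), giving known ground-truth informative bands.
* **Scatter** — per-sample multiplicative gain `1 + N(0, 0.05)` and
  additive offset `N(0, 0.01)`: exactly the artefact family SNV and MSC
  remove, so their benefit is testable.
* **Noise** — additive, sd `0.004 + 0.010 * ramp(λ)`, with the ramp rising
  linearly from 900 nm to the long-wavelength edge (detector noise grows
  toward 1000 nm; a ramp avoids a discontinuity).
* **Clipping** to [0, 1.5], not [0, 1]: panel-calibrated reflectance can
  exceed 1.

No published within-variety spectral variance exists for this design, so the
noise/scatter defaults are chosen for testability: strong enough that
pretreatment matters, weak enough that the task is solvable. The generator
does **not** simulate 2-D seed images, imaging optics, band-to-band
correlated noise, or instrument drift — so passing tests demonstrate the
pipeline's correctness and its qualitative behaviour under scatter and
noise, not field performance on real seeds.

## Pretreatments

All six map a spectra matrix to one of identical shape.

* **SG** — moving-window least-squares polynomial, default window 9 bands,
  order 2. A centred window must be odd, so the nearest odd width to the
  commonly quoted 8 is used and even widths are rejected with an explicit
  error. Edges use truncated asymmetric windows (same order) rather than
  shrinking the output.
* **FD** — symmetric difference `(R[i+1] − R[i−1]) / (λ[i+1] − λ[i−1])` on
  interior bands, one-sided two-point differences at the endpoints.
* **SNV** — per-spectrum centre/scale with an `n − 1` denominator; constant
  spectra raise an error naming the offending sample.
* **MSC** — reference = columnwise mean of the *training* partition; each
  spectrum is regressed on the reference by OLS and corrected
  `(x − β)/α`, exactly inverting affine scatter. Fitting the reference on
  training data only keeps the pipeline leakage-safe; `pooled_fit` (below)
  instead uses all samples.
* **FFT low-pass** — brick-wall zeroing of DFT bins with normalized
  frequency above 0.125 cycles per band interval (Nyquist = 0.5). Which
  normalisation the conventional "cutoff 0.125" refers to is ambiguous in
  the chemometric literature; cycles-per-sample is adopted and documented.
  Brick-wall zeroing makes the filter an exact projection (idempotent).
* **HT** — the Hilbert transform itself (imaginary part of the analytic
  signal; −90°/+90° phase shifts, amplitudes unchanged), applied to the
  mean-removed spectrum since the DC bin has no defined phase shift. For
  zero-mean spectra without Nyquist content, applying it twice negates the
  input.

## Selection methods

The class response throughout is a one-hot indicator matrix (PLS-DA /
MLR-DA), the standard chemometric coding for driving a regression criterion
(RMSECV) with class labels.

* **PLS-DA engine** — NIPALS partial least squares of the indicator matrix
  on the centred band matrix; RMSECV pools squared residuals over all
  indicator columns and samples under a stratified k-fold (default 5).
  Per-band importance is the Euclidean norm over classes of the regression
  coefficients from a full-data fit.
* **CARS** — `n_runs` = 50 sampling runs by default. Run *i*: draw a
  stratified 80% calibration subset without replacement; fit PLS-DA on the
  currently retained bands; keep the top `r(i)·p` bands by coefficient
  magnitude, where the enforced exponentially decreasing schedule
  `r(i) = a·e^(−k·i)` is pinned to retain all `p` bands at run 1 and exactly
  2 at the last run; re-sample that set with probability proportional to
  coefficient magnitude (without replacement, to the same count); record the
  retained set's RMSECV on the full data. The minimum-RMSECV run's subset is
  returned. The PLS component count is chosen once per invocation as the
  first minimum of inner-CV RMSECV over 1..10 components on the full band
  set and reused across runs (cost control). With without-replacement
  sampling to an unchanged count, the reweighted draw cannot shrink the set
  below the schedule, so the retained-count trace equals the schedule
  exactly; randomness enters through the calibration draws.
* **SPA** — from every candidate starting band, a chain of up to `m_max`
  (default 30, capped at `min(p, n − 2)`) bands is grown, each next band
  maximising the norm of its column's projection onto the orthogonal
  complement of the chain (computed by incremental Gram–Schmidt; a column
  numerically inside the span truncates the chain). Every (chain, prefix)
  is scored by stratified 5-fold CV RMSE of an OLS indicator fit with
  intercept, evaluated incrementally via a QR update so all prefixes of a
  chain cost one pass. The winner is the smallest prefix size whose RMSE is
  within a 1.01 factor of the global minimum — a concrete reading of the
  "RMSE stops improving" plateau rule — with ties going to the smaller
  RMSE and then the earlier chain.
* **Kaiser PCA** — bands are standardised (mean 0, sd 1, `n − 1`
  denominator) and the correlation matrix eigendecomposed; components with
  eigenvalue > 1 are retained (never fewer than one). The eigenvalue > 1
  rule is only meaningful on the correlation scale, hence the mandatory
  standardisation. Constant bands (zero range, or sd below 1e−12 of the
  column scale) are dropped with a warning and recorded in the model. Note
  that on pure-noise data roughly half the eigenvalues exceed 1 (the
  Marchenko–Pastur bulk straddles 1), so the rule measures dominance, not
  significance.

Tie-breaks everywhere are "first index wins"; selected bands are reported in
ascending wavelength order. All three methods are deterministic given their
seed.

## Classifiers

* **bayes** — naive Bayes with per-feature Gaussian *kernel density*
  class-conditional likelihoods (normal-reference bandwidth
  `1.06·σ·n^(−1/5)`, floored for constant features) and frequency priors.
* **svm** — SVC with the quadratic polynomial kernel `(x·y/γ + 1)²`
  (γ = scale), box constraint C = 1, one-vs-one multiclass.
* **knn** — 10 neighbours, Euclidean, equal weights (capped at n − 1 on
  tiny training sets).
* **el** — random-subspace committee: 30 linear discriminants, each on a
  random 40-feature subset (capped at the available feature count, with a
  log message), combined by majority vote with ties broken by summed
  posterior probability. The conventional "learning rate" parameter of
  ensemble toolboxes is recorded in the spec for provenance but is inert
  under subspace voting. LDA is the conventional subspace-ensemble base
  learner.
* **ann** — one hidden layer of 10 tanh units, softmax output, trained by
  backpropagation with the Adam optimiser (learning rate 0.01, up to 500
  epochs) and early stopping on a stratified 15% validation split of the
  training data (patience 50; disabled below 50 training samples, where a
  15% holdout is too small to be meaningful). The 0.01 learning rate
  matters: at the library default of 0.001 with short patience the network
  stops before the loss moves on ~200-sample spectra.

`svm`, `knn` and `ann` standardise features with training statistics inside
their pipeline; `bayes` and `el` are scale-adaptive by construction.

## Evaluation protocol

One stratified 3:1 split (per class, `ceil(3n/4)` to train) is shared by
every grid cell for comparability. Per cell: the pretreatment is fitted on
the training partition (only MSC is stateful) and applied to both
partitions; selection is fitted on the pretreated training partition; the
classifier is trained on the selected training features. Train and test
accuracies are fractions correct; the 5-fold CV accuracy is computed *within
the training partition*, refitting pretreatment and selection inside each
fold ("per-fold discipline"), and its pooled out-of-fold predictions form
the confusion matrix (rows = true classes). Selection fits are cached per
(pretreatment, selector, fold) since they are classifier-independent —
the 90-cell grid performs 18 selection fits per fold, not 90.

`pooled_fit=True` reproduces the common but leaky shortcut of fitting the
reference spectrum and the selector once on *all* samples and
cross-validating the full set; it logs an explicit leakage warning and
exists for comparison only.

A failed cell (any stage error) is caught, logged and recorded as a failed
entry; the grid always completes. The best cell maximises CV accuracy, with
ties broken by test accuracy and then lexicographically.

`correlate_trait` assigns each sample its class's trait value (e.g. crude
protein %) and computes the per-band Pearson correlation, reporting the full
vector and the maximising wavelength.

## Problem sizes used in the test and acceptance runs

The shipped tests run the statistical checks at desk scale, chosen once as
the smallest sizes at which the properties are comfortably testable: the
selector-recovery sweep uses 4 classes × 30 samples on 64 bands with three
planted bands over 20 replicate seeds (CARS at 30 runs); the
scatter-dominance sweep uses 5 classes × 20 samples on 48 bands over 20
seeds with a 2 × 2 × 2 grid; the full-grid smoke run uses 10 classes × 30
samples on the full 128-band grid. The default generator itself remains at
the full 10 × 120 × 128 design.

## Known limitations

* The generator's class effects are Gaussian bumps; real varietal
  differences also shift the red-edge position and change curvature, which
  no test here exercises.
* CARS component count is fixed per invocation; re-tuning it per run is
  more faithful to some published variants but 10× costlier.
* The subspace ensemble votes with equal weights; boosting-style variants
  (where a learning rate would act) are not implemented.
* ENVI support is read-only (BIL/BIP/BSQ, float32/uint16) and covers the
  header fields needed for cube + wavelength recovery, not the full header
  zoo.
* Published headline accuracies for this protocol on real seed images
  depend on data that was never deposited; nothing in this package asserts
  or reproduces those numbers.
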