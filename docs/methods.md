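# Methods

This note documents the models, defaults and numerical choices behind
`scrsdx`, what the synthetic data do and do not emulate, and the known
limitations.

## Spectral model and canonical grid

All spectra live on a shared strictly increasing wavenumber grid; the
canonical grid spans 319–3401 cm⁻¹ in 1019 uniform channels (step
≈ 3.027 cm⁻¹), matching a dispersive confocal Raman microscope with 532 nm
excitation.  Input on a different grid (e.g. 320–3400 cm⁻¹) is accepted
and linearly resampled; target channels outside the source range are
edge-filled and flagged.

A synthetic acquisition is

  I(ν̃) = s · c · Σ_k A_k f_k L_γ(ν̃ − ν̃_k) + B(ν̃) + ε(ν̃) + spike,

with `L_γ` a Lorentzian of FWHM 10 cm⁻¹ (typical cellular Raman
linewidth), `A_k` the band amplitude from a 27-band library (eight named
biomarker bands plus generic protein/lipid/nucleic-acid bands common to
all groups), `f_k` the group-specific concentration factor (HC ≡ 1),
`c ~ LogNormal(0, 0.15)` a per-cell latent concentration shared by that
cell's acquisitions (this is what makes per-cell averaging meaningful),
`s ~ LogNormal(0, 0.05)` a per-acquisition scale, `B` a random positive
5th-order polynomial (amplitude 0–5 × mean band height) emulating
autofluorescence, `ε ~ N(0, 0.02²)` additive noise, and single-channel
cosmic-ray spikes with probability 0.10 per acquisition and amplitude
50–140 × the noise scale (real cosmic rays are intense, frequently
CCD-saturating; the lower end keeps detection non-trivial).

Default effect directions at the biomarker bands: tryptophan, tyrosine and
glycerol elevated in all disease groups; phenylalanine and unsaturated
fatty acids elevated in mild ME and MS but reduced in moderate/severe ME;
cholesterol/CE reduced everywhere (most in MS); glycogen reduced in
mild/severe ME and MS; glucose reduced in all disease groups, lowest in
MS.  All non-unit factors are ≥ 15% away from 1 so that every injected
effect is individually recoverable at 100 cells/group.  (The literature
carries an internal tension on tyrosine — elevated in one reading,
reduced in another; the generator follows the elevated reading.)

## Clinical scores and symptom table

Fatigue Severity Scale scores are assigned by stratified inverse-CDF
sampling: mid-quantiles of a piecewise-linear CDF over (min, median, max)
are rounded and the middle order statistic is pinned, so the configured
group medians — ME/CFS 59 (range 44–63), MS 54 (16–63), HC 17 (11–37) —
are met *exactly* at the default sizes, not just in expectation.  The
rationale is testability: a worked value that is exact by construction
separates generator regressions from sampling noise.  Within ME/CFS,
sorted scores are allocated mild < moderate < severe (shuffled within
blocks) so fatigue tracks severity while the pooled median stays pinned.
SF-36 Physical Function respects the severity grading: mild ME strictly
above 25, moderate/severe strictly below.

The symptom table holds 63 ordinal variables (0 absent … 3 severe).
Entries are Binomial(3, p) draws with p = per-variable base intensity ×
group multiplier (HC 0.08, mild 0.45, moderate 0.60, severe 0.80, MS
0.50); a configurable third of variables is "ME-typical" (MS multiplier
halved), giving the severe-ME vs MS fold screen something real to find.
Missingness is MCAR at rate 0.05 — real questionnaire missingness is
unlikely to be MCAR, so passing tests say nothing about informative
missingness.

## Preprocessing chain

Order: resample → despike → polyline baseline → SNR QC → per-cell
averaging → vector normalization.  Normalizing after averaging is the
default (per-acquisition normalization before averaging is available);
the two orders do not commute and tests pin the default.

**Despiking** is within-spectrum (works on single acquisitions).  A
channel is a candidate when its leave-one-out quadratic residual — the
gap between the channel and the exact-cubic prediction from its ±2
neighbours — exceeds 8 × the local MAD (25-channel window) of those
residuals.  A candidate is confirmed as a cosmic ray by a scale-free
shape signature: a spike leaks into *both* neighbours' predictions,
driving their residuals below −0.38 × its own, while a genuine band top
(channel-centred or split between two channels) never does.  Flagged
channels are rebuilt by linear interpolation, or — for isolated gaps with
clean ±3 neighbourhoods — by an affine-exact stencil least-squares-matched
to the nominal 10 cm⁻¹ linewidth.  Consequences: recovery is exact
(≤ 1e−6) on locally linear signal; a spike landing exactly on a band top
retains an irreducible interpolation bias of ~0.08 × band amplitude, which
after 5–10-acquisition averaging leaves the SCRS within ~1.1% of its
spike-free twin (measured with a paired-seed oracle); spikes wider than
one channel are outside the detector's model.

**Polyline baseline**: the axis is split into 12 equal segments, the
minimum-intensity point of each segment plus the two terminal channels
become anchors, and the baseline is the piecewise-linear interpolant
(flat beyond terminal anchors, which on a full-axis fit never triggers).
Terminal anchors make the fit exact on linear backgrounds; the cost is
that a band sitting exactly on the first/last channel would be absorbed.
Corrected spectra are clipped at zero.

**QC**: SNR = max baseline-corrected intensity in 1420–1470 cm⁻¹ (CH₂
deformation) / SD in 1800–2600 cm⁻¹ (biologically silent); default
threshold 3.  Cells losing all acquisitions are dropped and logged.

**Normalization**: division by the L2 norm over the full axis (a
fingerprint-only region is selectable); unit norm is enforced to 1e−9.

## Band quantification

For each window (point centers ± 8 cm⁻¹ by default; explicit ranges
allowed) the chord joining the window's endpoint intensities is
subtracted before trapezoidal integration; a constant spectrum integrates
to exactly 0 and the statistic is first-order robust to residual broad
background.  At the canonical ~3 cm⁻¹ step a FWHM-10 band has ~3.3
channels per FWHM, so the trapezoid rule is sampling-limited to a few
percent of the dense-grid integral (0.5% is reached at FWHM ≥ 30); this
is a property of the grid, not of the implementation, and affects all
groups identically, so group contrasts are unaffected.  Two band-registry
profiles ship: the single-center biomarker panel (default) and a
multi-window profile for the aromatic amino acids; the two historic lists
disagree and both are kept.  Group comparisons use Welch's *t* (sample
SDs, Satterthwaite df) against HC with the conventional star coding.

## LDA views

Cell- or subject-level (subject = mean of its cells' SCRS) supervised LDA
with `solver="eigen"` and Ledoit–Wolf shrinkage of the within-class
covariance — with 1019 channels and far fewer cells per class the
unregularized within-class scatter is singular.  Explained-variance
fractions are eigenvalue ratios renormalized over the retained axes; axis
signs follow the convention that the largest-|coefficient| channel is
positive.  Feature selection ranks channels by |discriminant coefficient|
(ties toward the lower wavenumber).  This channel-space LDA is distinct
from the LDA base learner in the classifier, which operates on PCA
scores.  The confounder screen reports Pearson r of every covariate
(binary 0/1, categoricals one-hot) against every LD axis and flags
|r| > 0.75; zero-variance covariates give NaN and are never flagged.

## Stacked ensemble

Splits are stratified on the 5-class label; the default grouping keeps
all cells of a subject on one side (the leakage-prone per-cell split is
available as an explicit option).  A repeated-split mode cycles seeds so
every unit reaches the test set.  The transform (center/scale +
PCA to min(100, n−1, p) components) is fitted on train only.

Eight base learners run on the PCA scores: LDA, XGBoost, linear-kernel
SVM, RBF SVM, a single-hidden-layer MLP (size tuned over {8, 32, 64}),
random forest, in-repo MDA, and a gradient boosting machine.
Hyperparameter grids are deliberately small and fixed (most are
singletons); tuning uses repeated stratified CV (default 10-fold × 5
repeats; tests and examples use 3–5-fold × 1 as desk-scale settings).
Out-of-fold class probabilities, averaged over repeats, form the
n × (8 × C) meta-feature matrix; probabilities rather than hard labels
carry strictly more information.  The meta-learner is a shallow GBM.  For
test-time prediction each base learner is refit on the full training set.
Per-resample accuracy traces feed the 8×8 model-correlation matrix.

**MDA** (mixture discriminant analysis) is implemented in-repo: each
class a Gaussian mixture (default 3 subclasses) with one covariance
shared across all subclasses of all classes, fitted by EM with k-means
initialization, ridge-regularized pooled covariance, 100-iteration cap
and 1e−6 relative log-likelihood tolerance.  With one subclass per class
it reduces to classical LDA, which the tests verify.

Subject-level diagnosis aggregates cell predictions: `mean_prob` (argmax
of averaged probabilities), `majority` (modal label), or `meta_gbm` (a
GBM over per-subject class-fraction + mean-probability features, trained
on training subjects; used by default when ≥ 20 training subjects,
otherwise `mean_prob`).  Ties break by the fixed class order HC < MildME
< ModME < SevME < MS and are flagged.

Evaluation: row-percent confusion matrix, one-vs-rest sensitivity and
specificity (NaN where undefined), and exact Clopper–Pearson 95% binomial
intervals for accuracy (beta quantiles).

### The ensemble test-bed

The Raman generator's group effects are multiplicative mean shifts, on
which every base learner saturates, so ensemble-vs-single-learner
behaviour is probed on a dedicated feature-space cohort
(`make_mixture_classes`): three 4-feature blocks carry complementary
signal — weak random mean shifts (linear learners), mirrored Gaussian
cluster pairs with vanishing class means (mixture/flexible learners), and
per-class variance signatures (kernel/tree learners; invisible to any
shared-covariance model).  No single family is well-specified for all
three, which is the regime stacking is for.  The comparator for "best
single learner" is the held-out accuracy of the learner selected by
train-side CV — the choice actually available without peeking at the test
set; a test-set maximum over eight learners would be optimistically
biased.  The chance-level control runs the full spectral pipeline with
all band effects disabled and checks held-out 5-class accuracy against
20% within 3 SE.

## Clinical symptom statistics

Relative mean ordinal intensity per variable and group (missing excluded
pairwise); fold = (mean_sevME + ε)/(mean_MS + ε) with pseudo-count
ε = 0.05 guarding zero denominators; inclusion at fold ≥ 1.5.  Fisher
exact tests dichotomize at presence = entry ≥ 1 ("mild" or worse) — the
4-level-to-2×2 reduction is a design choice — with two-sided p by
hypergeometric enumeration (SciPy) verified against a brute-force
enumeration oracle, and Benjamini–Hochberg step-up adjustment
(significance at adjusted p < 0.05); variables with an empty group are
NaN and excluded from the test count m.  The heatmap export orders
variables by descending fold and subjects HC → mild → moderate → severe
→ MS, preserving missing entries as NaN.

## Problem sizes and determinism

Tests and the acceptance script run desk-scale configurations chosen as
the package's own defaults for automated verification: effect-direction
recovery at 100 cells/group (5 subjects × 20 cells, 3–5 acquisitions),
ensemble behaviour at 400 mixture samples × 10 seeds and 30-subject
spectral cohorts × 3 seeds, Fisher enumeration exhaustively at margins
≤ 10 plus 500 sampled tables at margins ≤ 30.  Every stochastic component
derives from a single seed through NumPy `SeedSequence` spawning;
identical configuration + seed reproduces cohorts channel-for-channel.
Independent child streams per component mean, e.g., clinical scores do
not change when spectra generation is switched off, and the cosmic-ray
stream is separate from the signal stream so spike-on/spike-off twin
cohorts differ only in spikes.

## Known limitations

- The generator omits instrument physics (CCD response, grating
  dispersion, wavenumber miscalibration), immune-cell-subtype mixtures,
  and batch effects beyond a per-acquisition scale; classifier accuracies
  on synthetic cohorts say nothing quantitative about real PBMC data.
- Cosmic-ray spikes are single-channel; multi-channel artifacts would
  need acquisition-pair comparison, deliberately out of scope.
- Baselines are positive polynomials; structured backgrounds (étaloning,
  substrate bands) are not modelled.
- The symptom model is conditionally independent given group; real
  symptom batteries are correlated, so BH behaves conservatively here
  relative to real data.
- Absolute concentration calibration, spectral unmixing, and vendor
  binary formats (SPC/WDF) are non-goals; a loader for deposited public
  datasets is an extension point, not a dependency.
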