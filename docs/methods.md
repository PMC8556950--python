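# Methods

`ramanstage` implements a chemometric pipeline for staging proliferating
human hepatocytes (ProliHHs) from single-cell Raman spectra of the
fingerprint region (300–1800 cm⁻¹).  Primary human hepatocytes (PHH,
passage 0) dedifferentiate toward a progenitor-like state as they are
passaged; the pipeline discriminates PHH from ProliHHs at passages 1 and 4
(P1, P4) and quantifies the biochemical band changes that drive the
discrimination.  Because single-cell Raman datasets of this kind are rarely
deposited, the package ships a synthetic generator that emulates the class
structure of such an experiment; every quantitative guarantee below is
demonstrated by parameter recovery on generated data.

## Synthetic data model

A spectrum is

    y(ν) = Σ_b A_b · J_b · G(ν; c_b, w) + B(ν) + ε(ν) + S(ν)

with, per band *b*, a Gaussian line `G` of FWHM `w = 15 cm⁻¹` (a typical
solid-phase biological linewidth) at the 13 centers reported for staged
hepatocytes (480, 831, 840–860 — synthesized as one peak at 850 —, 1003,
1080, 1172, 1206, 1265, 1300, 1337, 1440, 1658, 1744 cm⁻¹); per-cell
lognormal amplitude jitter `J_b` with unit mean and CV 0.15 (a choice — no
within-class variance is published for this system); a degree-3 polynomial
fluorescence background `B ≥ 0` whose mean level is `2×` the maximum peak
height, jittered per spectrum by U(0.7, 1.3) (autofluorescence dominates
the Raman signal in fixed cells); Gaussian noise `ε` with σ = 0.05 × max
peak height by default; and Poisson(0.3) cosmic-ray spikes `S` of width 1–2
channels and amplitude 10–100× the maximum peak height.  The axis is
300–1800 cm⁻¹ at 1 cm⁻¹ steps (1501 channels).

Class structure: the amplitude ratio between adjacent stages on trending
bands is 1.35.  Bands at 850, 1080, 1265, 1300, 1440, 1658 and 1744 cm⁻¹
decrease monotonically PHH → P1 → P4 (polysaccharide and lipid/protein
loss); 1003, 1206 and 1337 cm⁻¹ (phenylalanine, hydroxyproline, amide III)
increase monotonically; 480 and 831 cm⁻¹ are highest in PHH with P1 ≈ P4;
1172 cm⁻¹ is elevated only at P4.  The mid-stage amplitudes were balanced
so that the increasing and decreasing band groups carry comparable total
intensity: area normalization rescales each spectrum by its total
scattering, so an imbalanced design would dilute (or even invert) encoded
trends.  With the shipped amplitudes every encoded inequality survives
normalization with a ≥ 13 % between-class margin, which makes all trends
recoverable at n = 100/class with 5 % noise.

What the generator deliberately does **not** model: Raman cross-sections
and instrument response, wavenumber miscalibration, detector nonlinearity,
batch effects (batch and sampling-location metadata are assigned but carry
no signal), peak-shape asymmetry, and correlated noise.  Passing tests
therefore demonstrate correctness of the algorithms under the stated
statistical model, not performance on any particular instrument's data.

## Preprocessing

The chain is fixed: resample → despike → baseline-correct → area-normalize.

**Despiking.**  Cosmic spikes are 1–2 channel positive transients.  A
channel's spike score is the smaller of its largest lag-1/lag-2 rise on the
left and on the right, normalized by the MAD of the first differences
(Gaussian-consistent, 0.6745 factor); channels scoring above the threshold
(default 8) are replaced by linear interpolation of the nearest clean
neighbours.  This directional variant of the usual first-difference
z-score was chosen because the plain statistic flags both neighbours of a
spike and, on noiseless spectra where the MAD collapses, the flanks of
legitimate peaks; the min-of-sides form localizes each spike exactly and
provably never flags a channel that does not exceed both of its
neighbourhoods.  A scale floor of 1.5 % of the intensity range guards the
noiseless limit.  The operation is idempotent.

**Baseline.**  Asymmetric least squares on a Whittaker smoother:
iteratively reweighted ridge fit minimizing `Σ wᵢ(yᵢ−zᵢ)² + λ Σ(Δ²z)²`
with `wᵢ = p` above the fit and `1−p` below; defaults λ = 1e5, p = 0.01,
10 iterations (solved with a banded Cholesky factorization, O(n) per
pass).  Two guards: the estimate is clipped at zero, since a fluorescence
background cannot be negative, and an estimate whose maximum never reaches
`baseline_min_snr = 5` times the robust residual-noise scale is treated as
absent.  The second guard reflects a real statistical limit — an ALS
estimate below the noise floor is dominated by its own estimation error,
and subtracting it only distorts an already-flat spectrum — and it makes
the whole chain stable: rerunning preprocessing on its own output is a
numerical no-op (measured drift ~3e-16), because a corrected spectrum's
re-estimated baseline sits at the noise level and is gated off.  For
synthetic backgrounds at their default 2× level (≈ 40× noise) the gate
never suppresses a genuine baseline.  A degree-5 asymmetric polynomial fit
is available behind the same interface (`baseline_method="polynomial"`).

Known bias: with p = 0.01 the converged ALS fit sits ≈ 1.7σ below the true
background in noise-dominated regions (the asymmetric weighted-residual
balance point).  At the default noise and background levels this bounds the
baseline RMSE at ≈ 4 % of the mean background, within the 5 % recovery
guarantee; at lower background-to-noise ratios the relative error grows
accordingly.

**Normalization.**  Trapezoidal integral over the axis scaled to 1
(probability-density convention), so band areas are dimensionless fractions
of total scattering.  Negative post-baseline residuals are retained — not
clipped — to keep band integration unbiased.

## Band quantification

The 13 bands are integrated as closed wavenumber windows: center ± 10 cm⁻¹
for single-center bands, [840, 860] for the polysaccharide band, and
[821, 839] for 831 cm⁻¹ (truncated so it does not double-count channels
shared with its neighbour).  Window endpoints falling between channels
contribute linearly interpolated intensities, making integration exactly
additive over adjacent windows.  Groups are summarized by medians and
compared band-by-band with two-sided pooled-variance Student's t-tests
("Student's", not Welch, matching the field convention for this analysis),
annotated ns / * / ** / *** / **** at 0.05 / 0.01 / 0.001 / 0.0001 with the
0.05 boundary mapping to "ns".  No multiple-testing correction is applied
— the band set is small, fixed a priori, and the stars are descriptive.

## Chemometrics

With ~1500 channels and a few hundred spectra per class the within-class
scatter matrix is singular in channel space, so Fisher LDA is fitted in a
PCA subspace retaining 99 % of variance and its discriminant directions are
mapped back to channel space (unit norm) for interpretation; at most
`classes − 1` axes exist.  A still-singular within-class scatter is
ridge-regularized with ε = 1e-8 · trace(S_w)/dim, recorded on the model.
Determinism conventions: every principal/discriminant direction is oriented
so its largest-magnitude loading is positive, and ties at the top-loading
fraction boundary break toward the lower wavenumber.  The top-loading
extraction (`top_loading_wavenumbers`, default top 10 %) reports the
channels that drive each discriminant axis.

## Stacked classification

Spectra enter the classifiers as full preprocessed channel vectors (no band
reduction).  The data are split 75/25 (stratified by default; an
unstratified mode reproduces designs where per-class test counts deviate
from exact quarters).  Six base learners are tuned by repeated stratified
k-fold CV (default 10 folds × 5 repeats) maximizing accuracy:

| learner | grid |
|---|---|
| k-nearest neighbours | k ∈ {3, 5, 7, 9, 11} |
| PCA-LDA (shared-covariance Gaussian posterior) | — |
| PLS-DA (one-hot response, argmax decision) | components ∈ {2, 5, 10, 15, 20} |
| linear SVM (standardized) | C ∈ {0.01, 0.1, 1, 10} |
| RBF SVM (standardized) | C ∈ {0.1, 1, 10} × γ ∈ scale·{0.1, 1, 10} |
| random forest | 300 trees, √p features |

The SVMs emit softmax-transformed decision values as pseudo-probabilities
rather than Platt scaling: deterministic, argmax-consistent, and far
cheaper (Platt runs an internal CV per fit).  PLS-DA probabilities are the
shifted-nonnegative renormalized one-hot predictions (argmax-preserving).
The grids are intentionally lean — wider PLS/forest/GBM grids were
evaluated and never changed the selected model on this problem class while
multiplying runtime.

The second layer is a gradient boosting machine (learning rate 0.1, trees ∈
{50, 100, 150}, depth ∈ {1, 2}) tuned by the same CV on the base learners'
**out-of-fold** class probabilities, averaged over CV repeats — no base
learner ever predicts a spectrum it was fitted on within a repeat, which is
what lets the meta-learner see honest base-model behaviour.  Meta-features
are laid out learner-major (6 learners × n_classes columns); a hard-label
one-hot mode is available (`meta_mode="label"`).  At prediction time the
base learners score the new spectra, the meta-row is assembled in the
recorded class order, and GBM ties break toward the earlier class in that
order.

Evaluation is prediction-by-reference: confusion rows are model
predictions, columns are reference labels; sensitivity = diagonal /
reference-column total, specificity = correctly rejected negatives /
negatives, overall accuracy = trace / total, each reported to one decimal.
Every metric is a pure function of the matrix and is recomputed from it.

### The frozen reference report

`make_reference_report()` rebuilds the evaluation report from the published
three-class hepatocyte staging confusion counts (462 test spectra, classes
P1/P4/PHH).  The printed marginal metrics all follow from the printed
counts except the PHH specificity: the source prints 81.2 % where the
counts give 100·280/307 = 91.2 %.  The package reports the computed 91.2 %
and does not assert the printed value anywhere; the discrepancy is noted
here rather than silently "fixed" in either direction.

## Determinism

Every stochastic component — generator, splits, CV folds, forests, GBM —
is driven by explicit seeds recorded in bundles, manifests and reports.
Two pipeline runs from the same config produce byte-identical artifacts
(the structured log, which carries wall-clock timestamps, is the only
exception).

## Problem sizes used in the test suite and acceptance script

Statistical guarantees are demonstrated at sizes chosen to keep full runs
on one CPU comfortable while leaving the claims well-powered: band-trend
recovery at n = 100/class with 5 % noise; stacked-vs-single comparison on
ten generated studies at n = 200/class with 15 % noise under 5-fold ×
2-repeat CV; preprocessing guarantees at n = 30/class; reproducibility on a
full run at n = 24/class.  The acceptance script repeats the stacked
comparison on three generated studies.

## Known limitations

* The despike statistic assumes positive spikes (cosmic rays); negative
  transients would pass.
* ALS parameters are tuned for smooth, broad backgrounds; sharp background
  steps (e.g. substrate edges) would leak into the corrected spectrum.
* PLS-DA pseudo-probabilities are heuristic scores, not calibrated
  posteriors; they are meta-features, not quantities to interpret.
* Real-data accuracies depend on instrument, cell lots and acquisition
  protocol; the synthetic guarantees bound algorithmic, not biological,
  variability.
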