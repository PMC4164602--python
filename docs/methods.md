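# Methods

## Problem setting

Leaf ATR-FTIR spectra of plants from gypsum soils carry diagnostic
mineral and organic bands that separate three ecological strategies:
wide gypsophiles (gypsum specialists), narrow gypsum endemisms, and
gypsovags.  The package provides (i) a classifier of the three groups
from spectra, (ii) a PLS calibration of elemental composition against
spectra, (iii) band assignment for interpretable evidence, and (iv) a
synthetic-data generator so the whole chain is testable without any
instrument data.

## Data model and grid

Spectra are absorbance traces on a strictly monotonic wavenumber grid,
stored descending (4000 → 370 cm⁻¹).  The canonical grid has 1882
evenly spaced points over 4000–370 cm⁻¹ (spacing ≈ 1.93 cm⁻¹), matching
the classifier's input width; it is configurable, and `regrid` moves
spectra between grids by linear interpolation (extrapolation is an
error).  Absorbances are unitless, ATR-corrected; no instrument
corrections are modelled.

## Synthetic data generator

Each spectrum is

absorbance(ν) = offset + slope·(ν − ν_min)/(ν_max − ν_min)
              + Σ_b A_b · exp(−(ν − c_b)² / 2σ_b²) + ε(ν),

with ε iid Gaussian (default sd 0.01 absorbance).  Band centres follow
the reference library; σ defaults to ~10 cm⁻¹ for sharp mineral bands
and 40 cm⁻¹ for the broad O-H stretch.  Gaussian shapes were chosen
because only band positions and areas matter downstream; no claim of
physical lineshape is made.

Per-band amplitudes are drawn lognormally (unit mean, per-band CV) and
multiplied by a per-sample lognormal factor whose CV is 0.10 for
gypsovags and narrow endemisms and 0.25 for wide gypsophiles, encoding
the looser replication of the gypsum-rich spectra.  Group profiles:

* wide gypsophiles: gypsum bands (3522, 3400, 669, 597 cm⁻¹), broad
  sulphate near 1110 cm⁻¹, oxalate with high variability, attenuated
  organic bands;
* narrow endemisms: oxalate (1615, 1312, 780 cm⁻¹), no gypsum, moderate
  ester;
* gypsovags: strongest ester (1735 cm⁻¹) and CH₂, traces of sulphate
  only.  A fraction of gypsovag samples (default 3/17 ≈ 0.18, the
  replicate share of the one oxalate-bearing gypsovag species) also
  carries oxalate bands, which is the deliberate source of
  gypsovag/narrow confusability.

Default group sizes are 17/12/15 (44 samples, 14 pseudo-species with ~3
replicates each).  An optional "gypsophile without gypsum" variant
profile (strong amide, broad ~1600 cm⁻¹ absorption) exists but is off by
default so the three default classes stay cleanly separable.

The elemental table is linear in the drawn band areas (area =
amplitude·σ·√(2π)): S (%) = 0.055·(gypsum + other-sulphate areas);
Ca (%) = 0.09·(gypsum + oxalate + carbonate); Ash (%) = 2.0 +
0.30·(total inorganic); N (mg/g) = 2.2·(amide); C (%) = 48 − 0.55·Ash;
Na, Mg, P are weakly coupled analogues; K (mg/g) is lognormal (mean 12,
CV 0.3) independent of the spectrum by construction.  Multiplicative
noise (CV 0.04) is applied, so noiseless runs reproduce the linear maps
exactly.  All coefficients are plain config fields.

What the generator does **not** emulate: ATR optics, scattering and
water-vapour artefacts, baseline drift beyond a linear term,
species-level (14-way) fidelity, non-Gaussian lineshapes, and band
overlap chemistry in the crowded 1200–1000 cm⁻¹ region.  Passing tests
therefore demonstrate that the pipeline recovers structure *of this
kind*; they are not evidence about any particular instrument's data.

## Preprocessing

Stage 1 subtracts from each point the mean of a centred 101-point
window ("flattening"); at the spectrum ends the window shrinks
(truncates) by default, which is the natural reading of "50 values to
the left and 50 to the right"; a reflect policy is available for
sensitivity checks.  Flattening zeroes constant and, away from the
edges, linear trends, and is invariant to additive offsets.  Stage 2
divides by the maximum absolute value, giving values in [−1, 1] with at
least one value of magnitude 1; an all-zero derived spectrum (constant
input) is returned as zeros rather than failing.  Both stages are
symmetric, so grid orientation does not affect the result.

## Neural-network classifier

A fully connected feed-forward network with logistic activations on all
layers, reference architecture 1882–100–100–3.  Targets are one-hot
(1 for the presented group's node, 0 elsewhere).  Training is classic
online back-propagation on E = ½Σ(output − target)²: per-pattern
gradient steps at a fixed learning rate (0.05), patterns presented in a
freshly shuffled order each epoch, no momentum, weight decay, or early
stopping.  Weights start uniform on [−0.1, 0.1], biases at zero.  The
inner loop runs through BLAS rank-1 updates (`dger`) on transposed
weight views; tests assert bit-level equivalence with the plain
per-pattern update.

Evaluation is leave-one-out: for each case a fresh network is trained
on the other 43 cases and evaluated on the held-out one.  Per-fold
seeds derive from a SHA-256 digest of (run seed, sample id), and each
fold's training rows are ordered canonically by sample id, so results
are invariant to input row order.  The predicted group is the argmax
output node (ties to the lowest index).  Aggregates: confusion matrix
(rows = observed), per-node MAE and RMSE over all cases, compared
against the uniform-random baseline RMSE √(1/3) ≈ 0.577.

Routine runs use a reduced profile — hidden layers 20+20, 2000 epochs —
which keeps the protocol identical at a fraction of the cost; the
package's default `MLPConfig` remains the full 100+100 × 10,000
configuration.  A practical note on problem size: with tens of training
patterns and small logistic networks, the squared-error plateau at the
class base rates is escaped only after enough total updates
(epochs × patterns); very small demonstration sets need either more
epochs or a larger `init_scale` than the defaults.

## PLS calibration

PLS1 by NIPALS on mean-centred X and y: w ∝ Xᵀy, t = Xw, p = Xᵀt/tᵀt,
q = yᵀt/tᵀt, deflate, repeat.  The regression vector is
b = W(PᵀW)⁻¹q.  Validation is leave-one-out; the component count
(≤ 10) minimises RMSECV globally.  Reported metrics: R² = 100·(Pearson
correlation of CV predictions vs reference)², RMSECV, bias =
mean(pred − ref), and RPD = SD(reference)/SECV with SECV the ddof-1
standard deviation of bias-corrected CV residuals.  The squared-
correlation R² and the SECV definition are the standard chemometric
conventions consistent with an RPD quoted as SD/SECV.  No spectral
pre-treatment is applied inside PLS; raw or preprocessed matrices are
both accepted.  Degenerate folds that deflate early reuse their deepest
available component.

## Band assignment

Peaks are local maxima with configurable prominence (default 0.01
absorbance) and separation (10 cm⁻¹), via `scipy.signal.find_peaks`.
Each peak matches the nearest library band within 8 cm⁻¹ (≈ twice the
acquisition resolution); range-type bands match inside the range or
within tolerance of the nearer edge.  Compound flags require
corroborating evidence — gypsum needs both an O-H (3522/3400) and an
S-O (669/597) match, preventing broad water bands from flagging gypsum;
oxalate needs two of its three bands; carbonate two of three; ester and
amide one band each.  Prominence thresholds for expert-read spectra are
not knowable; the defaults are documented and configurable.

## Numerical and design choices

* Tie-break in class assignment: lowest node index, deterministic.
* All-zero normalisation input: returned unchanged (documented
  degenerate case).
* NIPALS stops early if X or y deflates below 1e-14 and reports the
  components actually extracted.
* Gradient correctness is asserted against central finite differences;
  near-zero gradient entries are compared absolutely (the ~1e-10
  roundoff of central differences makes relative comparison meaningless
  there).
* Seeds: a single `numpy.random.Generator` threads through the
  generator; classifier fold seeds are digest-derived (< 2³¹).

## Problem sizes used in the shipped analyses

The leave-one-out classification analyses shipped with the package run
the reduced 20+20 × 2000-epoch profile on the default 44-sample study;
classifier unit oracles use 4-per-class tight-cluster sets on coarse
(200–400 point) grids; the random-baseline and decoupling Monte-Carlo
checks use 10⁵ and 500 draws respectively.

## Known limitations

* The classifier is the era-appropriate plain backprop MLP; no
  regularisation, calibration, or modern optimisers.
* PLS component selection by global RMSECV minimum can be optimistic on
  very small n; no uncertainty intervals are reported.
* The generator's amplitudes are free parameters chosen for realism,
  not fitted to measured spectra; absolute metric values on synthetic
  data (e.g. R² per analyte) characterise the generator, not any field
  dataset.
* A composition-predicting network (regression rather than
  classification) is out of scope.
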