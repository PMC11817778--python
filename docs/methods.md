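# Methods

## Problem and model

A powder sample is a three-component mixture: peanut-skin powder plus two
starch adulterants (sweet potato, "A"; corn, "B"). The regression targets are
the mass percentages fA, fB and fC = fA + fB. Calibration works on FT-NIR
absorbance spectra over 10,000–4,000 cm⁻¹; each grid point ("variable") is one
wavenumber.

The synthetic generator assumes Beer–Lambert linear mixing: the ideal spectrum
of a sample is the mass-fraction-weighted sum of three pure-component spectra,
with the peanut-skin fraction equal to 1 − fC/100. Pure components are sums of
Gaussian bands. Band *positions* follow the qualitative spectroscopy of these
materials — peanut skin carries a cis-fatty-acid marker near 4,700 cm⁻¹, two
strong C–H overtone peaks between 5,000 and 6,000 cm⁻¹ and a smooth
8,200–8,400 cm⁻¹ region; the starches show more symmetric O–H/C–H bands with
partially overlapping positions. Band widths and heights are invented and are
claimed only to be *illustrative*: they give the three components distinct,
overlapping signatures of realistic magnitude (peak absorbance ≈ 0.1–0.7 AU).
They are a versioned, fully configurable fixture, not a measurement of real
materials.

## Study design emulated by the generator

* 15 total-adulteration levels: 40, 36, 30, 24, 20, 16, 12, 8, 6, 4, 3, 2, 1,
  0.5, 0 mass %.
* Five A:B ratios (1:1, 2:3, 3:2, 2:1, 1:3), one per level. The mapping of
  ratios to levels is not uniquely determined by the design constraints; the
  default pins level 40 → 2:3 and level 36 → 1:3 so the corn fraction reaches
  24% and 27% and forms a long-tailed distribution whose two largest values
  appear as boxplot outliers, and cycles the five ratios over the remaining
  levels. The mapping is fully overridable.
* 15 replicates per level → 225 samples.
* Grid: 1,557 equally spaced points from 10,000 to 4,000 cm⁻¹ (≈3.86 cm⁻¹
  spacing, the variable count of an 8 cm⁻¹-resolution FT-NIR export). The
  count is configurable; several tests use shorter grids for speed.

### Artifact model and defaults

Observed = gain·ideal + offset + slope·(ν − ν̄) + ε, per sample:

| parameter  | meaning                                   | default |
|------------|-------------------------------------------|---------|
| `gain_sd`  | sd of multiplicative scatter gain (about 1) | 0.05  |
| `offset_sd`| sd of additive baseline offset (AU)       | 0.01    |
| `slope_sd` | sd of linear baseline slope (AU per cm⁻¹) | 1e-6    |
| `noise_sd` | sd of white noise per wavelength (AU)     | 0.002   |

These magnitudes make raw-spectrum calibration visibly worse than
preprocessed calibration while leaving the task solvable — the regime the
pipeline is designed for. All randomness flows from one integer seed
(`numpy.random.default_rng`); identical seeds give bit-identical spectra.

What the generator does *not* emulate: Kubelka–Munk diffuse-reflectance
physics, instrument line shape, wavelength-dependent scatter, band
interactions between components, or replicate-scan averaging. Passing tests
therefore demonstrate the correctness and internal consistency of the
*algorithms*, not instrument-grade performance on real powders.

## Preprocessing

* **SNV**: per row, subtract the mean and divide by the sample sd (n−1).
* **MSC**: per row OLS fit x ≈ a + b·ref over all wavelengths; corrected row
  (x − a)/b. The reference is the calibration-set mean; the same reference
  transforms prediction spectra (no leakage). Note: the "MSC preserves the
  mean spectrum" identity is exact only when rows are exact affine
  distortions of a common shape; with residual noise it holds to first order.
* **SG**: local least-squares polynomial (window 11, order 2 by default),
  derivative scaled by the grid step so units are AU per (cm⁻¹)^deriv; the
  second-derivative mode shares window/order with smoothing. Edge policy:
  the polynomial fitted to the first/last window is evaluated at the edge
  positions (scipy's `interp` mode) rather than reflection padding, which
  would fabricate derivative artifacts at band edges. Because the storage
  axis runs along *descending* wavenumber, odd derivatives flip sign so that
  outputs are derivatives with respect to ν.

A caution surfaced by the noiseless tests: SNV and MSC divide each row by a
composition-dependent factor, so even on perfectly linear mixtures the
transformed spectra are *nonlinear* in (fA, fB) and a linear PLSR can no
longer fit them exactly. Raw and SG (linear operators) preserve exact
linearity. This is a property of the methods, not an implementation artifact.

## Kennard–Stone splitting and balance check

KS picks the pair at maximal Euclidean distance, then repeatedly the
unselected sample farthest from its nearest selected neighbour; ties break to
the lowest index, making the split fully deterministic. Distances are
computed on the preprocessed spectra being modelled. The default calibration
fraction is 70% rounded up — 158/67 on 225 samples. Balance is checked per
target with a two-sided Welch t-test plus Tukey boxplot summaries
(1.5·IQR fences); p > 0.05 is read as "no evidence of imbalance".

## CARS

Defaults: N = 50 runs, 80% Monte-Carlo sample draw, 5-fold RMSECV scoring.
Per run i: fit PLS on a random sample subset restricted to currently retained
variables; weights w_j = |b_j|/Σ|b_j|; keep the top K_i = max(2, ⌈r_i·p⌉)
variables where r_i = a·e^(−k·i) with a = (p/2)^(1/(N−1)), k = ln(p/2)/(N−1)
(so r₁ = 1 and r_N·p = 2); then draw K_i variables with replacement with
probabilities w and retain the distinct draws (floored at two variables).
Each round's subset is scored by shared-fold RMSECV on the full calibration
data; the minimum-RMSECV subset wins, ties resolved toward fewer variables,
then the earlier round. The internal PLS latent-variable count is chosen once
by 5-fold CV on the full calibration set (capped at 10) and held fixed across
rounds — this stabilizes the weights and bounds runtime.

## Calibration models

* **PLSR**: NIPALS PLS1 on mean-centered (not variance-scaled) data. The LV
  count 1–20 is chosen by 5-fold RMSECV; because NIPALS components are
  nested, one maximal fit per fold yields the coefficient vector for every
  truncation (B_k = W_k(P_kᵀW_k)⁻¹q_k), making the CV sweep cheap. Components
  beyond the effective rank are clamped. Ties go to the smaller LV count.
* **SVR**: ε-insensitive RBF support-vector regression, K(x, z) =
  exp(−g‖x−z‖²), ε = 0.1 (in mass-% units) unless configured otherwise.
  Inputs are mean-centered on calibration statistics only; no autoscaling.
* **Grid search**: c ∈ 2^(−2…10), g ∈ 2^(−12…2), √2 steps, exhaustive 5-fold
  RMSECV with a shared fold map; ties to smaller c then smaller g.
* **BKA-SVR**: the Black-winged Kite Algorithm searches log₂(c, g) inside
  c ∈ [0.01, 1024], g ∈ [1e-4, 1]. Each generation applies an *attacking*
  phase (multiplicative perturbations under a decaying 0.05·e^(−2(t/T)²)
  envelope, hovering or diving on a random switch) and a *migration* phase
  (heavy-tailed Cauchy steps toward or away from the current leader depending
  on a fitness comparison with a random peer). Selection is greedy, so the
  best-so-far trace is non-increasing; candidates are clipped to the box and
  non-finite objective values are rejected. Objective evaluations are cached.
  Correctness is gated behaviorally (bounds, monotone elitism, sphere-function
  convergence, matching/beating a discretized grid on an SVR objective)
  rather than by equation transcription. Pipeline defaults are population 10
  and 20 generations (≈300–400 cached RMSECV evaluations per target), the
  package's desk-scale budget; the optimizer itself is configurable and the
  behavioral tests exercise population 20 / 100 generations.

## Metrics and fold policy

R² = 1 − SSres/SStot (not squared Pearson). RMSEC/RMSEP are computed strictly
on calibration/prediction rows; an adversarial "split-aware" sentinel test
verifies no pathway mixes them. RMSECV pools out-of-fold residuals,
folds being contiguous blocks of a seeded shuffle; every model in one
comparison shares the fold map so RMSECV values are comparable. Reports are
written as CSV and JSON twins with metrics at 4 decimals.

## Pipeline and problem sizes

Order: preprocess → Kennard–Stone split → CARS per target → fit models.
For stateful preprocessing (MSC) the split is computed on whole-set-referenced
spectra, then the transform is refitted on calibration rows for modelling.
`run_all` persists every stage artifact plus a manifest (config hash, seed,
library versions) that suffices to replay a run; the simulated-spectra stage
is reloaded from disk when its configuration hash is unchanged.

Default problem sizes: the full study (225 × 1,557) for the model-comparison
experiment and the acceptance script; shorter grids (200–800 points) and
fewer replicates in unit tests and examples where the property under test
does not depend on the grid length. The full model comparison completes in
roughly half a minute on one CPU.

## Known limitations

* The endmember band tables are illustrative, not fitted to real materials;
  absolute RMSEP values on synthetic data are not transferable to instrument
  data.
* Linear mixing ignores matrix effects and particle-size-dependent band
  shapes; preprocessing effect sizes (e.g. SG vs raw) are correspondingly
  mild.
* The SVR tube width ε is fixed rather than tuned; ν-SVR is not implemented.
* CSV headers print wavenumbers to 3 decimals, so a written grid is recovered
  to ~5·10⁻⁴ cm⁻¹ on read (absorbance and targets round-trip at full
  precision).
* Alternative selectors (SPA, UVE, GA) and split strategies (SPXY, duplex)
  are out of scope.
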