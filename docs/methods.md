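# Methods

## The problem

In vitro soak testing of neural interfaces (ECoG microarrays in phosphate-
buffered saline) produces one electrochemical impedance spectroscopy (EIS)
sweep per recording channel per soaking day: impedance magnitude (and phase)
over a logarithmic frequency grid. Watching dozens of channels and decades of
frequency across many days is tedious and hard to automate. This package
reduces each day to a single scalar, smooths the resulting series, and
forecasts the next day's value — an early-warning signal for electrode
degradation.

## Day-factor reduction

For the channel-averaged spectrum of day *d* with magnitudes Z_k (ohms) at
frequencies f_k (Hz),

    DF_raw(d) = Σ_k w_k · |log Z_k(d)|,   w_k = 1/f_k by default,
    DF(d)     = DF_raw(d) / DF_raw(1),

so DF(1) ≡ 1 and the series reads as relative drift from the day-1 reference
state. Notes:

- **Weights.** Reciprocal-frequency weights make the low-frequency end of the
  sweep — the band most sensitive to charge-transfer changes at the
  electrode/electrolyte interface — dominate the sum. The scheme is
  pluggable (`WeightScheme`): custom positive per-frequency weights can
  emphasise any band; this is also the hook for future phase-based variants.
- **Log base.** The natural logarithm is the default; base 10 is available.
  The base rescales raw values and slightly reweights days in the normalized
  series, so it is part of the configuration and pinned in all tests.
- **Units.** |log Z| is unit-dependent; magnitudes are consumed in ohms and
  the CSV reader enforces that column.
- **Channel handling.** The pipeline averages magnitudes over channels first
  (arithmetic mean, not complex-impedance mean) and reduces the average; a
  per-channel convenience loop exists for inspecting individual sites.
- The normalized value at day *d* is computed as DF_raw(d)/DF_raw(1); both
  numerator and denominator use their own day's magnitudes.

## Spline smoothing

Soaking days are sparse and can have calendar gaps of several days, so the
discrete DF points are converted to a continuous signal by a cubic spline
evaluated on a uniform fractional-day grid (`samples_per_day`, default 10 —
the resampling density is configuration, and every test pins it).

- Default mode is an **interpolating** not-a-knot cubic spline: parameter-free
  and exactly reproducing the measured DF at the knot days (resampled knot
  values are pinned to the originals to remove round-off). With fewer than
  four days the spline degree drops to the maximum the data support.
- A **pchip** mode (monotone shape-preserving cubic) avoids overshoot between
  sparse points; a **smooth** mode (smoothing spline with residual budget
  `smoothing`) tolerates noisy DF points and reaches the interpolant as
  `smoothing → 0`.
- Gaps are spanned on the calendar axis rather than re-indexed, so a 3-day
  gap really is three days of spline, and the forecaster sees calendar time.
- Because the spline is fitted once to the whole series (as in the original
  workflow), samples just before a training cutoff already bend toward the
  following knots. Walk-forward training is leakage-free with respect to the
  *samples* it is given, but the smoothing step itself is global; this is a
  property of the method, not an implementation accident.

## One-day-ahead LSTM forecasting

A univariate LSTM is trained as a sequence-to-sequence one-step-ahead
regressor on the z-scored training segment (inputs x[1..T−1], targets
x[2..T]) and generates the held-out day closed-loop: the state consumes the
full training sequence, then each predicted sample is fed back as the next
input until the day's `samples_per_day` samples exist. Open-loop prediction
is not the default; walk-forward uses a fresh model per predicted day (no
warm starts), trained only on samples at positions ≤ n−1.

Protocol defaults (`ForecasterConfig`): 200 hidden units, 250 epochs, Adam
with initial learning rate 0.005, gradient threshold 1, no early stopping,
full-sequence batches, mean-squared-error loss, mandatory seed.

Implementation choices:

- The LSTM is implemented directly in numpy (fused-gate forward, full
  backpropagation through time). Backprop is validated against central finite
  differences in the test suite (≤1e-4 relative).
- Initialization: Glorot-uniform input and readout weights, orthogonal
  recurrent blocks per gate, zero biases with a unit forget-gate bias — all
  drawn from `numpy.random.default_rng(seed)`, so identical (signal, config,
  seed) triples give bitwise-identical predictions.
- Gradient clipping rescales the global L2 norm of all parameter gradients to
  the threshold.
- Standardization uses the training segment's mean and standard deviation; a
  constant segment (std < 1e-12) uses std = 1, which preserves the constant
  and avoids division by zero.
- An optional `max_history_days` window restricts training to the trailing
  days (the "fewer soaking days may predict better" knob); default unlimited.
- A deterministic persistence baseline (repeat the last observed value) is
  provided for comparison and as a test oracle on degenerate signals.

## Accuracy statistics

For each predicted day, with A the actual and B the predicted sample vector:

- **AFS** (accuracy of final state):
  `100 · (1 − |B_end − A_end| / (max(DF_actual) − min(DF_actual)))`, where the
  range is over the **entire** actual smoothed signal. The absolute value is
  the default (AFS ≤ 100); `signed=True` evaluates the raw difference, under
  which under-prediction can exceed 100%. AFS below 0 (error beyond the full
  range) is reported, not clamped. Zero signal range raises an error.
- **ACC** (accuracy of correlation coefficients): `100 · |corr(A, B)|`,
  Pearson, computed on the predicted day's segment only — the two signals
  coexist only there. Zero variance in either segment makes the correlation
  undefined; it is reported as undefined (`None`), never as 0. Whether the
  covariance uses the population or sample normalization cancels in the
  ratio.

## Synthetic soak tests

Because real microarray datasets of this kind are rarely released, the
generator builds spectra from a Randles equivalent circuit — solution
resistance R_s in series with (charge-transfer resistance R_ct ∥ double-layer
capacitance C_dl), optional Warburg element in series with R_ct:

    Z(f) = R_s + 1 / ( 1/(R_ct + (1−j)·σ_w/√(2πf)) + j·2πf·C_dl )

Drift is a per-day trajectory of circuit parameters; each channel sees the
day's magnitude through multiplicative log-normal noise (σ = 0.05 by default
— channel spreads in soak tests are scale-proportional; a relative additive
mode exists). Phases come from the noise-free circuit.

Presets (11 soaking days, day-1 parameters R_s = 2 kΩ, R_ct = 4 MΩ,
C_dl = 1.2 nF, giving |Z(1 kHz)| ≈ 134 kΩ, inside the 50–250 kΩ window of
real ECoG recording sites):

- `stable` — constant parameters; 32 channels; 1 Hz–2 MHz sweep (30 points).
- `dip_then_rise` — R_ct dips ~30% on days 5–7 (C_dl up ~15–20%), recovers,
  then rises ×2 and ×3.5 on days 10–11; 32 channels; 0.1 Hz–10 kHz sweep.
- `fluctuating` — brief dips on days 5 and 9, final-two-day rise ×1.8/×3;
  16 channels; 0.1 Hz–10 kHz sweep.

What the generator does *not* emulate: constant-phase-element dispersion,
electrode-area scaling, trial-to-trial drift within a day, instrument
artifacts. Passing tests therefore demonstrate the pipeline's algebra,
determinism and forecasting behaviour on circuit-shaped drift, not
performance on any particular physical device.

## Problem sizes and numerical choices

- The walk-forward evaluations in the tests use 11-day signals at 10 samples
  per day (101 samples), the full 200-unit/250-epoch protocol for the
  accuracy checks, and a shrunk 32-unit/50-epoch profile for protocol-shape
  checks where accuracy is not at stake.
- DF and PCA are validated against independent scalar-loop and
  covariance-eigendecomposition oracles at 1e-12/1e-10 tolerances; spline
  knot reproduction at 1e-9.
- PCA orientation: frequencies are observations, days variables, so the first
  right singular vector yields one coefficient per day; the loading's sign is
  fixed (first nonzero entry positive) before normalizing to the first
  coefficient, which makes the sign choice immaterial. A centered matrix that
  is exactly zero raises a degenerate-input error.
- CSV floats are written with `%.17g` (round-trip exact for doubles); file
  outputs are byte-reproducible given identical configuration and seed.

## Known limitations

- Closed-loop generation compounds one-step errors; days that start a new
  trend (the final rise) are predicted worst — consistent with walk-forward
  forecasting generally.
- The forecaster is univariate; amplitude+phase multivariate forecasting and
  phase-based day factors are out of scope (the weight-scheme hook is the
  extension point).
- No proprietary potentiostat formats (Gamry DTA, nanoZ exports) are parsed;
  the long CSV is the interchange format.
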