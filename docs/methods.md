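# Methods

This note documents the models, defaults and numerical choices behind
`pasa`, and what the synthetic cohort does and does not establish.

## Analysis pipeline

**Calibration.** A tissue waveform at optical wavelength λ is divided by
the peak-to-peak amplitude of the blackbody reference recorded at the same
λ.  Because both channels see the same laser pulse, any per-wavelength or
shot-to-shot energy factor cancels exactly; the calibrated waveform is
dimensionless.  A blackbody peak-to-peak below 1e−12 is treated as a dead
reference channel and rejected, and calibrating an already-calibrated
record is an error (the `calibrated` flag is set only by `calibrate`).

**Welch spectra.** PSDs use a 5 μs moving Hamming window with 60% overlap
(Welch's method, `scipy.signal.welch`).  Numerical conventions, chosen
where the textbook description leaves latitude:

- window length in samples = round-half-up(window_seconds × fs); at the
  default 2.5 GS/s this is exactly 12 500 samples (200 kHz resolution);
- hop = floor(0.40 × window samples); FFT length = window length (no zero
  padding, no unstated interpolation);
- per-segment constant (mean) detrending, so no spurious DC term leaks
  into the 1 MHz band edge;
- one-sided density scaling; tiny negative round-off values are clipped
  to 0.

An optional time gate restricts analysis to a region of interest; the
default is the full record.  A brute-force segment-loop implementation in
the test suite pins the estimator to these conventions at 1e−10 relative
error.

**PAPCS.** Per wavelength, PSDs of the measurement positions are averaged
and rows stacked in increasing-wavelength order.  This PSD-level position
average is used for the spectrogram display/export; the feature path
instead averages at the relative-APSD level (below), which is the order
stated for the quantitative analysis.  Both are exposed.

**Relative APSD.** The area of power spectral density (APSD) is the
trapezoidal integral of the PSD over [f₀, f₁] = [1, 8] MHz, with PSD
values linearly interpolated at the exact cutoffs when they fall between
grid points.  The analysis band reflects where absorber-scale spectral
energy lies while excluding low-frequency system noise and high-frequency
measurement noise.  Relative APSD divides by the APSD of the same
position's reference-wavelength (λ₀ = 690 nm) record; a non-positive
reference APSD is rejected rather than propagated.  Relative APSD is
computed per position, then averaged across the two positions.  λ₀ and
the cutoffs are configurable.

**Band features.** Fixed wavelength sets: lipid 1200–1240 nm (5), collagen
1300–1340 nm (5), lipid overtone 1600–1700 nm (11); their union, ordered
by band then wavelength, gives the 21 feature columns.  Column order is
irrelevant to the RBF kernel; the sorted convention is just a convention.

**Statistics.** Two-sided unpaired t-tests, pooled-variance Student by
default with a Welch option; star annotation at 0.05/0.01/0.001.  The
pooled-variance default matches the common convention of the statistics
package used in the original analysis workflow; no multiple-testing
correction is applied, so stars are per-comparison.  Zero-variance equal
groups return t = 0, p = 1 with a `degenerate` flag.

**Classification.** C-type SVM with the RBF kernel, one-vs-one voting for
prediction (the standard multiclass C-SVM construction in scikit-learn)
and one-vs-rest decision scores for ROC.  Protocol, with rationale where
the choice was open:

- stratified three-fold outer split (stratification guarantees every class
  appears in each training fold, which plain random thirds do not);
- per-fold z-scoring fit on the training fold (default on: RBF distances
  on raw, differently-scaled APSD ratios are seed-fragile);
- per-fold grid search over C ∈ 2^{−5..15}, γ ∈ 2^{−15..3} (the standard
  powers-of-two search) by inner stratified 3-fold CV, ties broken toward
  the smallest C then smallest γ (prefer the simpler model — this makes
  the selection deterministic);
- test predictions pooled over folds into a confusion matrix with
  *predicted* labels on rows and *true* labels on columns; per-class
  accuracy is the column-normalised diagonal;
- ROC per class from pooled one-vs-rest decision values (not
  probabilities), AUC by trapezoid.

## Forward simulator

The simulator emulates the acquisition that the analysis assumes: 51 scan
wavelengths plus the 690 nm reference, 2.5 GS/s sampling, 25 μs records
(62 500 samples, ≥ 9 Welch windows), a 1–20 MHz transducer band
(4th-order Butterworth, zero-phase), per-wavelength pulse energy
0.1–0.5 mJ with 5% multiplicative shot fluctuation shared between the
tissue and blackbody channels of a wavelength, 64-shot averaging, two
measurement positions, and additive Gaussian noise.

**Tissue model.** A phantom is a set of spherical absorbers with a common
composition (lipid / collagen / water volume fractions).  Class means
(mean ± sd, truncated at 0, rescaled if the sum exceeds 1):

| fraction | normal | SCC | BCC |
|---|---|---|---|
| lipid | 0.30 ± 0.05 | 0.20 ± 0.05 | 0.12 ± 0.05 |
| collagen | 0.35 ± 0.05 | 0.25 ± 0.05 | 0.17 ± 0.05 |
| water | 0.25 ± 0.05 | 0.25 ± 0.05 | 0.25 ± 0.05 |

The normal > SCC > BCC ordering of lipid and collagen is the biological
structure the method detects; the effect sizes are this package's choice
of a realistic separation at the study's group sizes and are
config-exposed.  Water is class-independent so the 690 nm reference is
approximately class-neutral.

**Chromophore spectra** are built-in analytic stand-ins in arbitrary
relative units — Gaussian peaks at 1210 nm and a 1720 nm overtone shoulder
(lipid), 1320 nm with a weak 1700 nm rise (collagen), and a small monotone
rising water term — shaped to reproduce the qualitative band structure of
the literature absorption spectra.  All three are small and flat at
690 nm.  Real tabulated spectra can be substituted via
`ChromophoreSpectrum.from_table`.

**Pulse model.** A sphere of radius *a* emits a bipolar pressure pulse of
duration 2a/c with amplitude ∝ μₐ(λ) × pulse energy × a.  The default
shape is one smooth sine cycle over the pulse duration, whose spectral
peak lies near the characteristic frequency c/(2a); the classical
sawtooth N-wave is available (`pulse_shape="nwave"`) but its spectral peak
sits at ≈ 0.66·c/(2a), i.e. a third below the characteristic frequency,
which is why it is not the default for a simulator whose radii are chosen
by target frequency.  Radii are log-uniform over 0.125–0.5 mm
(c/(2a) = 1.5–6 MHz at c = 1500 m/s), which keeps ≥ 80% of the filtered
signal energy inside the 1–8 MHz analysis band; arrival times are uniform
over 2–20 μs.  The second measurement position views the same absorbers
with a deterministic ±5% path-length jitter (seeded per sample/position,
independent of wavelength, as a fixed geometry must be).

**Noise and averaging.** 64-shot averaging is modelled as dividing the
additive-noise standard deviation by √64 — exactly equivalent for
additive Gaussian noise and 64× cheaper than explicit draws.  The default
raw-noise σ = 0.01 (detector units) puts the post-averaging noise floor
well below the weak 690 nm reference signal, so the APSD ratio stays
signal-dominated.

**The 690 nm reference** is emitted by the simulator like any scan
wavelength, using the extrapolated (flat, low) chromophore absorptions.
How the reference shot was physically acquired outside the scan range of
the tuning source is not specified in the original protocol; the simulator
simply provides a consistent low-absorption reference channel.

**Determinism.** Every operation is a pure function of its inputs and a
seed; a dataset simulated twice with the same seed is bit-identical, and
iteration is over the canonical class order so the per-class content does
not depend on the order in which counts are passed.

**What the synthetic cohort does not show.** It contains no acoustic
attenuation or propagation, no depth-dependent fluence, no histological
heterogeneity, and its class separations are constructed, not measured.
Passing tests on it demonstrate that the pipeline recovers the structure
the generator encodes (ordering, significance, feature dimensionality,
classifier behaviour) — not that real tissue attains any particular
accuracy.  Correspondingly, the published spectra magnitudes and AUCs of
the ex vivo cohort are not reproduction targets; only the bundled
per-sample prediction table is replayed exactly.

## Published-table replay

The bundled CSV transcribes the per-sample test predictions of the ex vivo
cohort.  Accuracies are recomputed from the predictions and rounded
half-up to one decimal, matching the published precision.  Two quirks of
the source table are preserved rather than repaired (see
`pasa/benchmark.py`): the same 13 test-sample identifiers appear in all
three cycles (inconsistent with a rotating three-fold test set), and the
cycle-3 / 1210 nm summary cell prints 69.2% while its own per-sample
predictions give 76.9% (10/13) — the replay reports the recomputed value,
and consequently a 1210 nm mean of 71.8 rather than the printed 69.2.

## Problem sizes used in tests and the acceptance script

The replay runs on the 13 × 12 prediction grid as published.  Synthetic
end-to-end checks use the study's cohort size (12/15/12) at full
acquisition settings; unit-level signal tests use a reduced 0.25 GS/s /
25 μs configuration, which preserves every analysis-relevant property
(the Welch window still holds 1250 samples and the transducer band is far
below Nyquist) while keeping individual records small.  These sizes are
the package's test design choices.

## Known limitations

- The forward model is linear and monopole-like: no nonlinear absorption,
  no frequency-dependent acoustic attenuation, no transducer angular
  response, no speckle-like absorber interference statistics.
- Chromophore spectra are qualitative stand-ins; absolute relative-APSD
  magnitudes in the simulator are not comparable to measured tissue.
- The SVM protocol fixes fold stratification; the original random
  two-thirds/one-third rotation cannot be reconstructed from what is
  published (see the identifier quirk above).
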