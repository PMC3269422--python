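# Methods

This note documents the models implemented in `speechdecode`, the
numerical choices behind them, and what the synthetic benchmarks do and do
not establish.

## Auditory spectrogram

The peripheral model is a bank of 4th-order gammatone FIR filters
(`scipy.signal.gammatone`) with log-spaced centre frequencies over
180–7,000 Hz (128 channels ≈ 1/24-octave spacing; ERB-scaled bandwidths,
which at these frequencies are close to the ~1/12-octave constant-Q
target). Each channel's envelope is the Hilbert magnitude, compressed by a
cube root (a standard stand-in for cochlear compression; the exact
peripheral nonlinearity is a documented choice, not a claim of
equivalence), and averaged over 10 ms frames (100 Hz). The floor is 0; no
dB conversion is applied on the analysis path — per-channel normalization
exists only for display. Downsampling to 32 channels averages
non-overlapping groups of 4 adjacent channels; group centres are geometric
means, which keeps the axis exactly log-spaced.

## Modulation-energy representation

The modulation analysis is a separable 2-D complex wavelet transform of
the spectrogram:

* **Temporal (rate) kernels**: causal gamma-windowed complex exponentials
  `(rt)² e^(−3.5rt) e^(j2πrt)` for r ∈ {1, 2, 4, 8, 16, 32} Hz, truncated
  at 4/r s and normalized to unit peak gain. The kernel mean is subtracted
  so that the DC response is exactly zero: without this, the energy model's
  defining property — a *constant* magnitude for a constant-rate AM input —
  fails, because DC leakage beats against the carrier. Convolution extends
  the signal into the past at its initial frame value, so a temporally
  constant input produces exactly zero modulation energy and onsets reflect
  real envelope change only.
* **Spectral (scale) kernels**: complex Gabors on the log-frequency axis,
  `e^(−x²/2σ²) e^(j2πsx)` with σ = 0.6/s octaves, s ∈ {0.5, 1, 2, 4, 8}
  cyc/oct. Pairing the analytic temporal kernel with the Gabor versus its
  conjugate selects the two spectro-temporal quadrants: negative rates
  respond to upward frequency sweeps, positive to downward.

The full form takes magnitudes per (scale, signed rate, frequency, time)
and averages the frequency axis down to 32 channels (5×12×32 = 1,920
channels). The rate–scale form averages the *complex* output over
frequency before the magnitude (60 channels); the rate-only form applies
the temporal kernels alone and averages channel magnitudes over frequency
(6 unsigned channels — pure temporal filtering is not direction
selective). Scales of 4–8 cyc/oct are meaningful only against the
128-channel axis (the 32-channel axis undersamples them spectrally), which
is why the full transform is computed at 128 channels before frequency
reduction.

## Magnitude-only inversions

**Modulation → spectrogram.** Alternating projections: from a random
nonnegative initialization, apply the filterbank (implemented in the 2-D
DFT domain with padding that covers the longest kernels), substitute the
target magnitudes while keeping the current phases, invert by regularized
filterbank summation (Σ H̄ₖZₖ / (Σ|Hₖ|² + ε), ε = 10⁻³ of the peak), clip
to nonnegative, and iterate (default 200 iterations, stop when the
successive-iterate correlation changes by < 10⁻⁴). The result is averaged
over `n_init` random initializations (default 100) and is deterministic
given the seed. Two limitations are inherent: the temporal kernels are
zero-mean, so the static (temporal-DC) part of the spectrogram lies in the
null space and is unrecoverable from magnitudes; and the truth-correlation
of the iterate is not the algorithm's objective, so it need not improve
monotonically — the iterations monotonically reduce the magnitude
mismatch instead, which is what the tests assert. On synthetic 1-s words
the averaged round trip correlates r ≈ 0.7–0.8 with the source.

**Spectrogram → waveform.** Griffin–Lim-style projections over the
gammatone bank: from seeded noise, filter into channels, rescale each
channel's analytic signal to the (uncompressed) target envelope, and
resynthesize by summation. Deterministic given the seed; intended for
inspection, not perceptual quality.

## Neural preprocessing

Common-average referencing subtracts the mean of the good channels from
each good channel; flagged-bad channels neither contribute to nor receive
the reference. Band power uses a zero-phase Kaiser-window FIR band-pass
(designed for ≥ 60 dB stopband; the order is capped by the filtfilt
padding constraint and logged), the squared Hilbert envelope (an
amplitude switch exists), polyphase resampling to the 100 Hz frame rate,
and whole-session z-scoring (a per-trial option is deliberately not the
default: the models consume the continuous standardized signal). The
band-pass + Hilbert envelope is used in place of empirical-mode
decomposition variants of envelope extraction, whose sifting is too
under-specified to reproduce exactly; the downstream models consume only
the envelope contract. The multiband variant covers 1–300 Hz in 30 bands
of 10 Hz (inclusive band-edge counting; the last band is clipped at
300 Hz).

## Stimulus reconstruction

Each stimulus channel is decoded independently from all electrodes and
100 forward lags at 10 ms (the decoder reads the response window that
*follows* the stimulus frame; the sign convention is fixed and documented
here because either direction is defensible). Fitting is greedy forward-
stagewise coordinate descent: at each iteration the coordinate with the
largest norm-normalized gradient moves by a fixed step ε = 10⁻³ × (target
SD / feature SD); the iterate with the best validation MSE is kept, and
fitting stops after 50 consecutive non-improving iterations (or
`max_iter`, default 10⁵). This yields sparse weights and performs implicit
variable selection, so no electrode preselection is needed. The per-channel
problems are mathematically independent; the implementation updates all
channels in one loop for cache efficiency. Run to convergence with the
patience disabled, the estimator agrees with ridge regression at small
penalty (prediction r > 0.99 on the test problems).

Monte Carlo cross-validation partitions whole trials (never frames) into
80/10/10 train/validation/test splits; partitions are a pure function of
the plan's seed, so two stimulus spaces compared under one plan see
byte-identical splits — the paired-comparison contract. Weights are
averaged over resamples; the per-weight SE is the SD across resamples and
the t-ratio its mean/SE. Informative electrodes require |t| > 2.5 and
Benjamini–Hochberg FDR survival at α = 0.05 (two-sided p from a t
distribution with n_resamples − 1 df) on any weight; the screen refuses
fewer than 3 resamples. Accuracy is Pearson r per stimulus channel,
aggregated on the Fisher-z scale; zero-variance channels are excluded and
counted. Rate-resolved accuracy projects both reconstruction and original
through the rate–scale filterbank, correlates the 60 components, and
averages over scale and sweep direction (6 unsigned rates).

## STRF encoding models

The encoding map is dense: steepest-descent on the training MSE with an
exact line search per step (no fixed learning rate to tune), early-stopped
on validation MSE with patience 50. Cross-validation uses 20 resamples by
default. Frequency tuning zeroes inhibitory weights and sums over lags;
SEs are propagated by recomputing the tuning transform per resample and
taking the SD (exact, no delta-method approximation). Rate tuning has
three routes: *nonlinear* (excitatory lag-sum of a rate-only or full
modulation STRF, signed rates folded), *linear filterbank* (the
spectrogram STRF filtered by the modulation bank, complete convolution,
per-kernel energies normalized so rate channels are comparable), and
*linear MTF* (RMS of the 2-D Fourier modulus over half-octave rate bands
and spectral frequencies ≤ 8 cyc/oct). The two linear routes agree at
r > 0.9 on random smooth STRFs whose modulation content spans the rate
range; keeping the convolution tails and normalizing by kernel energy is
what makes the time-domain route comparable to the Fourier-domain one.
Tuning peaks are significant (t > 2) local maxima separated by more than
half an octave; closer maxima merge keeping the larger amplitude, exact
ties resolving to the lower frequency. Octave distance on rate axes uses
log₂ of the rate ratio. Ensemble curves max-normalize per site and average
over sites with forward prediction r > 0.1; tuning spread is the fraction
of 32 log-spaced frequency bins over 180–7,000 Hz containing at least one
site's peak.

## Word identification

DTW alignment uses per-frame cost 1 − Pearson correlation between
frequency columns, the symmetric step pattern (diagonal/horizontal/
vertical), no band constraint, and diagonal-preferring tie-breaks; the
similarity is the Pearson correlation of the path-aligned vectorized
spectrograms. Identification runs on spectrograms smoothed by a 2-D box
filter (500 ms × 2 octaves, edge-truncated), while pairwise similarity
matrices are computed before smoothing. The identification rank counts
candidates scoring strictly below the correct word (ties count half) over
n − 1; chance mean is 0.5. The median-rank null shuffles the
reconstruction-to-word assignment (default 10,000 shuffles); both the
plug-in p (proportion ≥ observed, which can be exactly 0) and the
conservative (k+1)/(n+1) variant are reported. The ROC sweeps a similarity
threshold with matched pairs as positives and mismatched pairs as
negatives. The dynamic program is numba-compiled; tests verify it against
exhaustive path enumeration on small inputs.

## Synthetic benchmarks

Units are either *envelope-locked* — response = frequency-tuning profile
(1–5 Gaussian bumps on the log-frequency axis, bump count weighted toward
2–5, positions uniform in log frequency) applied to the 32-channel
spectrogram, low-passed at a corner rate (default 8 Hz) to emulate the
loss of envelope synchronization at fast rates — or *modulation-energy* —
response = rate-tuning profile (log-Gaussian around a peak rate) applied
to the rate-only modulation representation, hence phase-invariant.
Formant-word stimuli superpose 2–3 slowly drifting resonances under a
syllable-rate (≤ 4 Hz) envelope with 20 ms attacks (≥ 16 Hz onset
content), durations 0.3–1 s; each presentation is followed by 0.8 s of
silence so every trial covers the decoder's 1 s lag window. Trial noise is
white Gaussian in z-units (AR(1) optional); fixture signal-to-noise levels
are chosen for test discriminability, not biological realism — per-trial
high-gamma SNR in real recordings is not well quantified. Everything is a
pure function of (configuration, seed).

What the benchmarks show: the estimators recover planted structure
(filters at SNR ≥ 10, informative electrodes, tuning peaks and their
histogram), the decoder's accuracy profile across modulation rates
separates envelope from energy coding in the expected directions, and the
identification statistics are calibrated (mean rank 0.5 for uninformative
reconstructions; uniform randomization p under the null). What they do not
show: performance on real ECoG, where noise is structured, electrodes are
correlated, and the true encoding is neither purely linear nor purely
energy-based. The linear-sufficiency limit (accuracy → 1 as noise → 0)
additionally requires a population whose tuning spans the stimulus space;
with few, broadly tuned units accuracy saturates below 1 regardless of
noise.

## Problem sizes

The shipped tests and the acceptance script run at desk scale as a design
choice: populations of 10–32 units, 12–47 words of 0.3–1 s, 2–4
cross-validation resamples, coordinate-descent budgets of a few thousand
iterations (the default `max_iter = 10⁵` remains available for full
convergence studies), and 1,000 Monte Carlo targets for rank calibration.
The statistical contracts being tested (calibration, recovery, directional
contrasts) are scale-free; larger runs tighten the estimates without
changing the conclusions.
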