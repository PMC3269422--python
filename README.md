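# speechdecode

Reconstructing speech representations from multichannel cortical recordings.

When people listen to speech, field-potential electrodes over auditory
cortex pick up band-power responses (most informatively in the high gamma
band, ~70–150 Hz) that track the sound's spectro-temporal content. This
package implements the full analysis chain for asking *which* auditory
features such a neural population encodes:

1. **Audio frontend** — the waveform is passed through a 128-channel
   gammatone filterbank (log-spaced 180–7,000 Hz), envelope-extracted,
   compressed, and framed at 100 Hz into an auditory spectrogram `S(f, t)`,
   optionally downsampled to 32 channels. A bank of causal spectro-temporal
   modulation filters (scales 0.5–8 cyc/oct, rates ±1–32 Hz) turns the
   spectrogram into a phase-invariant modulation-energy representation
   `M(s, r, f, t)` (1,920 channels full; 60 rate–scale; 6 rate-only).
   Magnitude-only inversions back to a spectrogram and to a waveform are
   provided (iterative projection / Griffin–Lim-style phase retrieval).
2. **Neural preprocessing** — common-average referencing, band-pass +
   Hilbert band power, resampling to the 100 Hz stimulus frame rate,
   z-scoring, and trial alignment.
3. **Stimulus reconstruction (decoding)** — the linear map

   `Ŝ(f, t) = Σ_n Σ_τ g(τ, f, n) · R(t + τ, n)`

   with 100 lags at 10 ms, fitted per stimulus channel by greedy coordinate
   descent with early stopping (sparse solutions), evaluated by Monte Carlo
   cross-validation over trials with Fisher-z-averaged Pearson accuracy,
   resampled parameter SEs/t-ratios, FDR-screened informative electrodes,
   and rate-resolved accuracy through the modulation filterbank.
4. **STRF encoding models** — per-electrode filters `r(t) = Σ_x Σ_u
   h(x, u) s(x, t−u)` in spectrogram (3,200 parameters), full modulation
   (192,000), or rate-only (600) spaces, fitted by early-stopped gradient
   descent; frequency and rate tuning curves, peak rules (t > 2, half-octave
   separation), ensemble curves, and tuning spread.
5. **Word identification** — dynamic-time-warping similarity between
   reconstructed and actual word spectrograms, percentile identification
   ranks (chance mean 0.5), a 10,000-shuffle randomization null for the
   median rank, ROC curves, and pairwise similarity matrices.
6. **Synthetic data** — ground-truth populations mixing envelope-locked
   (linear) and modulation-energy (nonlinear, phase-invariant) units over
   synthetic formant words, so every stage is testable without patient
   recordings.

## Worked example

Simulate a modulation-energy population, decode it in both stimulus
spaces, and compare rate-resolved accuracy:

```python
import numpy as np
from speechdecode.decoder import CvPlan, FitConfig
from speechdecode.synthetic_data import make_benchmark

ds, manifest = make_benchmark("energy", seed=5, n_stimuli=20,
                              stimulus_params={"duration_s": 0.8})

# (helpers.cv_rate_accuracy in tests/ shows the full driver)
# spectrogram-space decoding, then rate-scale-space decoding with the
# identical trial partitions:
plan = CvPlan(n_resamples=3, seed=11)
cfg = FitConfig(step_scale=5e-3, max_iter=3000)
```

On this fixture the run prints rate-resolved accuracies (rates 1, 2, 4, 8,
16, 32 Hz):

```
spectrogram space : [0.999 0.996 0.935 0.703 0.593 0.524]
rate-scale space  : [0.978 0.986 0.926 0.933 0.907 0.848]
```

Both spaces decode slow modulations almost perfectly, but only the
modulation-energy space preserves rates ≥ 8 Hz — the signature of
amplitude-based (phase-invariant) temporal coding that a linear
envelope model cannot capture.

Identification of 47 synthetic words from a low-noise mixed population
(`tests/test_pipeline.py`) reaches a median identification rank of 0.96
against a chance level of 0.5.

## Command line

A thin CLI wraps the library: `speechdecode spectrogram`, `modulation`,
`invert`, `highgamma`, `decode-fit`, `synth`, `identify-demo`. Run
`speechdecode --help` for options.
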