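"""Synthetic stimuli and ground-truth neural populations.

The generator emulates the statistical structure the decoding analysis
assumes about auditory cortex band-power responses: units are z-scored
100 Hz time series that are either

* *envelope-locked*: a linear function of the 32-channel auditory
  spectrogram through a frequency-tuning profile with 1-5 peaks on the
  log-frequency axis, low-passed at a corner rate (default 8 Hz) to emulate
  the loss of envelope synchronization above that rate; or
* *modulation-energy*: a linear function of the (phase-invariant) temporal
  modulation energy of the stimulus through a rate-tuning profile peaked at
  one modulation rate.

Trial noise is additive white Gaussian in z-units at a controllable level
(an AR(1) option provides temporally correlated noise). Stimuli are
amplitude-modulated tones, frequency sweeps, or formant-like synthetic
words (2-3 resonances, syllable-rate envelope plus fast onsets, 0.3-1 s).
All generators are pure functions of (configuration, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .audio_frontend import (
    AuditorySpectrogram,
    Waveform,
    compute_auditory_spectrogram,
    compute_modulation_representation,
    downsample_spectrogram,
)
from .exceptions import InvalidConfigError, InvalidInputError
from .neural_preproc import NeuralResponseMatrix, zscore_columns

__all__ = [
    "SyntheticUnit",
    "SyntheticDataset",
    "generate_stimuli",
    "make_units",
    "simulate_population_responses",
    "make_benchmark",
]

DEFAULT_FS = 16000
FRAME_RATE = 100.0
N_FREQ_DECODE = 32
PEAK_COUNT_WEIGHTS = (0.15, 0.30, 0.25, 0.20, 0.10)  # 1..5 peaks; most sites 2-5


@dataclass
class SyntheticUnit:
    """Ground-truth response model for one simulated electrode."""

    kind: str  # "envelope_locked" | "modulation_energy"
    true_filter: np.ndarray
    noise_sd: float = 0.1
    corner_or_peak_rate_hz: float = 8.0
    freq_peaks_hz: list = field(default_factory=list)

    def __post_init__(self):
        if self.kind not in ("envelope_locked", "modulation_energy"):
            raise InvalidConfigError(f"unknown unit kind {self.kind!r}")
        if self.noise_sd < 0:
            raise InvalidConfigError("noise_sd must be nonnegative")
        self.true_filter = np.asarray(self.true_filter, dtype=float)


@dataclass
class SyntheticDataset:
    """A fully reproducible stimulus/response benchmark."""

    stimuli: list  # Waveform per presented trial (in trial order)
    labels: list
    responses: NeuralResponseMatrix
    trial_table: pd.DataFrame
    ground_truth: list
    seed: int
    stim_features: dict  # name -> [n_channels, n_frames] aligned matrices
    spectrograms: list  # per-trial 32-channel AuditorySpectrogram
    freq_centers_hz: np.ndarray | None = None


# ---------------------------------------------------------------------------
# Stimuli
# ---------------------------------------------------------------------------


def _am_tone(rng, params):
    fs = params.get("fs", DEFAULT_FS)
    dur = params.get("duration_s", 1.0)
    f0 = params.get("carrier_hz", 1000.0)
    rate = params.get("rate_hz", 4.0)
    depth = params.get("depth", 1.0)
    phase = params.get("mod_phase", 0.0)
    t = np.arange(int(round(dur * fs))) / fs
    env = 1.0 + depth * np.sin(2 * np.pi * rate * t + phase - np.pi / 2)
    return env * np.sin(2 * np.pi * f0 * t), fs


def _sweep(rng, params):
    fs = params.get("fs", DEFAULT_FS)
    dur = params.get("duration_s", 1.0)
    f0 = params.get("start_hz", 300.0)
    f1 = params.get("end_hz", 3000.0)
    t = np.arange(int(round(dur * fs))) / fs
    return signal.chirp(t, f0, dur, f1, method="logarithmic"), fs


def _syllable_envelope(rng, n, fs, n_syllables):
    """Syllable-rate gating with fast (>= 16 Hz content) onsets."""
    env = np.zeros(n)
    edges = np.linspace(0, n, n_syllables + 1).astype(int)
    attack = int(0.02 * fs)  # 20 ms attack -> onset energy at fast rates
    for a, b in zip(edges[:-1], edges[1:]):
        seg = b - a
        gap = int(0.12 * seg)
        body = seg - gap
        e = np.ones(body)
        ramp = min(attack, body // 3)
        if ramp > 1:
            e[:ramp] = np.linspace(0, 1, ramp)
            e[-ramp:] = np.linspace(1, 0, ramp)
        env[a:a + body] = e * (0.7 + 0.3 * rng.random())
    return env


def _formant_word(rng, params):
    fs = params.get("fs", DEFAULT_FS)
    dur = params.get("duration_s") or rng.uniform(0.3, 1.0)
    n = int(round(dur * fs))
    t = np.arange(n) / fs
    n_formants = rng.integers(2, 4)
    n_syllables = rng.integers(1, 4)
    x = np.zeros(n)
    for _ in range(n_formants):
        fc = np.exp(rng.uniform(np.log(250.0), np.log(3500.0)))
        drift = rng.uniform(-0.4, 0.4)  # octaves over the word
        freq = fc * 2.0 ** (drift * t / dur)
        phase = 2 * np.pi * np.cumsum(freq) / fs
        x += rng.uniform(0.5, 1.0) * np.sin(phase + rng.uniform(0, 2 * np.pi))
    env = _syllable_envelope(rng, n, fs, int(n_syllables))
    x = x * env + 0.01 * rng.standard_normal(n)
    return x, fs


_STIMULUS_KINDS = {"am_tone": _am_tone, "sweep": _sweep, "formant_word": _formant_word}


def generate_stimuli(kind: str, params: dict | None, n: int, seed: int):
    """Generate ``n`` waveforms of one stimulus family, reproducibly."""
    if kind not in _STIMULUS_KINDS:
        raise InvalidConfigError(f"unknown stimulus kind {kind!r}")
    params = dict(params or {})
    fs = params.get("fs", DEFAULT_FS)
    for key in ("carrier_hz", "start_hz", "end_hz"):
        if key in params and not (0 < params[key] < fs / 2):
            raise InvalidConfigError(f"{key}={params[key]} outside (0, Nyquist)")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        samples, fs_out = _STIMULUS_KINDS[kind](rng, params)
        out.append(Waveform(samples, fs_out))
    return out


# ---------------------------------------------------------------------------
# Units
# ---------------------------------------------------------------------------


def _freq_tuning_profile(rng, freq_centers):
    """1-5 Gaussian bumps on the log-frequency axis."""
    n_peaks = int(rng.choice(np.arange(1, 6), p=PEAK_COUNT_WEIGHTS))
    logf = np.log2(freq_centers)
    w = np.zeros(freq_centers.size)
    peaks = []
    for _ in range(n_peaks):
        c = rng.uniform(logf[0], logf[-1])
        width = rng.uniform(0.25, 0.5)  # octaves
        w += rng.uniform(0.5, 1.0) * np.exp(-0.5 * ((logf - c) / width) ** 2)
        peaks.append(float(2.0**c))
    return w, peaks


def _rate_tuning_profile(rng, rates, peak_rate):
    logr = np.log2(np.asarray(rates, float))
    return np.exp(-0.5 * ((logr - np.log2(peak_rate)) / 0.6) ** 2)


def make_units(
    n_units: int,
    seed: int,
    kind_mix: float = 0.7,
    noise_sd: float = 0.1,
    corner_rate_hz: float = 8.0,
    peak_rates=(2.0, 4.0, 8.0, 16.0, 32.0),
    freq_centers=None,
    rates=(1.0, 2.0, 4.0, 8.0, 16.0, 32.0),
):
    """Draw a mixed population; ``kind_mix`` is the envelope-locked fraction."""
    if freq_centers is None:
        freq_centers = np.geomspace(180.0, 7000.0, N_FREQ_DECODE)
    rng = np.random.default_rng(seed)
    units = []
    n_env = int(round(kind_mix * n_units))
    for i in range(n_units):
        if i < n_env:
            w, peaks = _freq_tuning_profile(rng, freq_centers)
            units.append(
                SyntheticUnit(
                    "envelope_locked", w, noise_sd, corner_rate_hz, peaks
                )
            )
        else:
            peak = float(rng.choice(peak_rates))
            w = _rate_tuning_profile(rng, rates, peak)
            units.append(SyntheticUnit("modulation_energy", w, noise_sd, peak))
    return units


# ---------------------------------------------------------------------------
# Responses
# ---------------------------------------------------------------------------


def _lowpass_frames(x, corner_hz, frame_rate):
    if corner_hz >= frame_rate / 2:
        return x
    b, a = signal.butter(2, corner_hz / (frame_rate / 2))
    return signal.filtfilt(b, a, x)


def simulate_population_responses(
    stimuli,
    units,
    frame_rate: float = FRAME_RATE,
    seed: int = 0,
    labels=None,
    n_trials: int = 1,
    ar1: float = 0.0,
    isi_s: float = 0.8,
) -> SyntheticDataset:
    """Simulate z-scored population responses to a stimulus list.

    Each stimulus is presented ``n_trials`` times (trials concatenated in
    stimulus order, repeated) followed by ``isi_s`` of silence (long enough that every trial covers the decoder's 1 s lag window), as in a
    word-presentation session; a trial spans the word plus its silence. The
    noiseless response of a unit is its stimulus space's representation
    weighted by ``true_filter``; Gaussian noise (optionally AR(1) with
    coefficient ``ar1``) is added per trial and the session is z-scored per
    unit.
    """
    if not stimuli:
        raise InvalidInputError("need at least one stimulus")
    if labels is None:
        labels = [f"w{i:02d}" for i in range(len(stimuli))]

    specs32, word_frames, rate_only, rate_scale = [], [], [], []
    for w in stimuli:
        n_word = int(w.samples.size // (w.sample_rate_hz // int(frame_rate)))
        pad = np.zeros(int(round(isi_s * w.sample_rate_hz)))
        wp = Waveform(np.concatenate([w.samples, pad]), w.sample_rate_hz)
        s128 = compute_auditory_spectrogram(wp)
        s32 = downsample_spectrogram(s128, N_FREQ_DECODE)
        specs32.append(s32)
        word_frames.append(n_word)
        rate_only.append(
            compute_modulation_representation(s32, reduced_form="rate_only")
        )
        rate_scale.append(
            compute_modulation_representation(s128, reduced_form="rate_scale")
        )
    freq_centers = specs32[0].freq_centers_hz

    order = list(range(len(stimuli))) * n_trials
    spec_cat = np.hstack([specs32[i].values for i in order])
    ronly_cat = np.hstack([rate_only[i].values for i in order])
    rscale_cat = np.hstack([rate_scale[i].flatten_channels() for i in order])
    frames_per = [specs32[i].n_frames for i in order]
    trial_index = np.concatenate(
        [np.full(f, k) for k, f in enumerate(frames_per)]
    )

    rng = np.random.default_rng(seed)
    T = spec_cat.shape[1]
    resp = np.empty((T, len(units)))
    for u_idx, u in enumerate(units):
        if u.kind == "envelope_locked":
            drive = u.true_filter @ spec_cat
            drive = _lowpass_frames(drive, u.corner_or_peak_rate_hz, frame_rate)
        else:
            drive = u.true_filter @ ronly_cat
        sd = drive.std()
        if sd > 0:
            drive = drive / sd
        noise = rng.standard_normal(T) * u.noise_sd
        if ar1 > 0:
            noise = signal.lfilter([1.0], [1.0, -ar1], noise)
            noise *= np.sqrt(1 - ar1**2)
        resp[:, u_idx] = drive + noise
    resp = zscore_columns(resp)

    onsets = np.concatenate([[0], np.cumsum(frames_per)[:-1]]) / frame_rate
    table = pd.DataFrame(
        {
            "trial_id": np.arange(len(order)),
            "label": [labels[i] for i in order],
            "onset_s": onsets,
            "offset_s": onsets
            + np.array([word_frames[i] for i in order]) / frame_rate,
            "word_frames": [word_frames[i] for i in order],
        }
    )
    responses = NeuralResponseMatrix(
        resp, frame_rate, standardized=True, trial_index=trial_index
    )
    return SyntheticDataset(
        stimuli=[stimuli[i] for i in order],
        labels=[labels[i] for i in order],
        responses=responses,
        trial_table=table,
        ground_truth=list(units),
        seed=seed,
        stim_features={
            "spectrogram32": spec_cat,
            "rate_only6": ronly_cat,
            "rate_scale60": rscale_cat,
        },
        # word-only portions (silence trimmed), for identification analyses
        spectrograms=[
            AuditorySpectrogram(
                specs32[i].values[:, : word_frames[i]], freq_centers, frame_rate
            )
            for i in order
        ],
        freq_centers_hz=freq_centers,
    )


# ---------------------------------------------------------------------------
# Benchmarks
# ---------------------------------------------------------------------------

_FIXTURES = {
    # (stimulus kind, n_stimuli, n_units, envelope fraction, noise_sd)
    "words": ("formant_word", 47, 16, 0.7, 0.1),
    "envelope": ("formant_word", 24, 12, 1.0, 0.1),
    "energy": ("formant_word", 24, 12, 0.0, 0.1),
}


def make_benchmark(fixture: str = "words", seed: int = 0, **overrides):
    """Standard test populations with a ground-truth manifest.

    ``words``: mixed population over 47 synthetic words for end-to-end
    decoding and identification; ``envelope``: purely envelope-locked
    population (linear-model sufficiency); ``energy``: purely
    modulation-energy population (the fast-rate contrast between decoding
    spaces). Returns ``(dataset, manifest)``.
    """
    if fixture not in _FIXTURES:
        raise InvalidConfigError(f"unknown fixture {fixture!r}")
    kind, n_stim, n_units, mix, noise = _FIXTURES[fixture]
    n_stim = overrides.get("n_stimuli", n_stim)
    n_units = overrides.get("n_units", n_units)
    noise = overrides.get("noise_sd", noise)
    n_trials = overrides.get("n_trials", 1)
    params = overrides.get("stimulus_params", {})

    stimuli = generate_stimuli(kind, params, n_stim, seed)
    units = make_units(
        n_units,
        seed + 1,
        kind_mix=mix,
        noise_sd=noise,
        corner_rate_hz=overrides.get("corner_rate_hz", 8.0),
        peak_rates=overrides.get("peak_rates", (2.0, 4.0, 8.0, 16.0, 32.0)),
    )
    dataset = simulate_population_responses(
        stimuli, units, seed=seed + 2, n_trials=n_trials
    )
    manifest = {
        "fixture": fixture,
        "seed": seed,
        "n_stimuli": n_stim,
        "n_units": n_units,
        "noise_sd": noise,
        "units": [
            {
                "kind": u.kind,
                "noise_sd": u.noise_sd,
                "corner_or_peak_rate_hz": u.corner_or_peak_rate_hz,
                "freq_peaks_hz": u.freq_peaks_hz,
            }
            for u in units
        ],
    }
    return dataset, manifest
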