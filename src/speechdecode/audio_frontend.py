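"""Auditory spectrogram and spectro-temporal modulation representations.

The frontend converts a sound waveform into the two stimulus spaces that the
decoding and encoding models operate on:

* an *auditory spectrogram* ``S(f, t)``: the compressed amplitude envelope
  in a bank of 128 gammatone channels with log-spaced centre frequencies
  over 180-7,000 Hz, framed at 100 Hz, and optionally downsampled to 32
  channels by averaging groups of adjacent channels;
* a *modulation-energy representation* ``M(s, r, f, t)``: the magnitude of a
  2-D complex wavelet analysis of the spectrogram with spectral scales of
  0.5-8 cycles/octave and temporal rates of 1-32 Hz. Rates are signed:
  negative rates respond to upward frequency sweeps and positive rates to
  downward sweeps. Reduced forms average out the frequency axis
  (``rate_scale``, 60 channels) or use pure temporal filters
  (``rate_only``, 6 unsigned rates).

Both representations are magnitude-only; approximate inversions back to a
spectrogram (iterative projection over the modulation filterbank) and to a
waveform (Griffin-Lim-style alternating projections over the gammatone
filterbank) are provided for inspection and playback.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import signal

from .exceptions import InvalidConfigError, InvalidInputError

__all__ = [
    "Waveform",
    "AuditorySpectrogram",
    "ModulationRepresentation",
    "DEFAULT_RATES_HZ",
    "DEFAULT_SCALES_CYC_PER_OCT",
    "compute_auditory_spectrogram",
    "downsample_spectrogram",
    "compute_modulation_representation",
    "invert_modulation_to_spectrogram",
    "invert_spectrogram_to_waveform",
]

DEFAULT_RATES_HZ = (1.0, 2.0, 4.0, 8.0, 16.0, 32.0)
DEFAULT_SCALES_CYC_PER_OCT = (0.5, 1.0, 2.0, 4.0, 8.0)
DEFAULT_FRAME_RATE_HZ = 100.0
DEFAULT_FMIN_HZ = 180.0
DEFAULT_FMAX_HZ = 7000.0


@dataclass
class Waveform:
    """A mono sound pressure waveform."""

    samples: np.ndarray
    sample_rate_hz: int

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise InvalidInputError("waveform contains non-finite samples")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate_hz


@dataclass
class AuditorySpectrogram:
    """Nonnegative envelope representation over log-spaced frequency channels.

    ``values`` has shape ``[n_freq, n_frames]``; the floor is 0 (no dB
    conversion on the analysis path).
    """

    values: np.ndarray
    freq_centers_hz: np.ndarray
    frame_rate_hz: float = DEFAULT_FRAME_RATE_HZ

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.freq_centers_hz = np.asarray(self.freq_centers_hz, dtype=float)
        if self.values.ndim != 2:
            raise InvalidInputError("spectrogram values must be 2-D [n_freq, n_frames]")
        if self.values.shape[0] != self.freq_centers_hz.size:
            raise InvalidInputError("frequency axis does not match values")
        if np.any(self.values < 0):
            raise InvalidInputError("spectrogram values must be nonnegative")
        if np.any(np.diff(self.freq_centers_hz) <= 0):
            raise InvalidInputError("frequency centers must be strictly increasing")

    @property
    def n_freq(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def channel_spacing_octaves(self) -> float:
        f = self.freq_centers_hz
        return float(np.log2(f[-1] / f[0]) / (f.size - 1))

    def normalized_for_display(self) -> np.ndarray:
        """Per-channel max normalization (display only, never analysis)."""
        peak = self.values.max(axis=1, keepdims=True)
        peak[peak == 0] = 1.0
        return self.values / peak


@dataclass
class ModulationRepresentation:
    """Magnitude output of the 2-D modulation filterbank.

    Shapes by ``reduced_form``:

    * ``full``: ``[n_scale, n_signed_rate, n_freq, n_frames]``
    * ``rate_scale``: ``[n_scale, n_signed_rate, n_frames]`` (complex output
      averaged over frequency before the magnitude)
    * ``rate_only``: ``[n_rate, n_frames]`` with unsigned rates (pure
      temporal filters are not direction selective)
    """

    values: np.ndarray
    rates_hz: np.ndarray
    scales_cyc_per_oct: np.ndarray
    reduced_form: str
    frame_rate_hz: float = DEFAULT_FRAME_RATE_HZ
    freq_centers_hz: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.rates_hz = np.asarray(self.rates_hz, dtype=float)
        self.scales_cyc_per_oct = np.asarray(self.scales_cyc_per_oct, dtype=float)
        if np.any(self.values < 0):
            raise InvalidInputError("modulation energy must be nonnegative")
        expected_ndim = {"full": 4, "rate_scale": 3, "rate_only": 2}
        if self.reduced_form not in expected_ndim:
            raise InvalidConfigError(f"unknown reduced form {self.reduced_form!r}")
        if self.values.ndim != expected_ndim[self.reduced_form]:
            raise InvalidInputError("values shape inconsistent with reduced form")

    @property
    def n_frames(self) -> int:
        return self.values.shape[-1]

    @property
    def n_channels(self) -> int:
        return int(np.prod(self.values.shape[:-1]))

    def flatten_channels(self) -> np.ndarray:
        """View as a [n_channels, n_frames] feature matrix."""
        return self.values.reshape(self.n_channels, self.n_frames)


# ---------------------------------------------------------------------------
# Gammatone filterbank spectrogram
# ---------------------------------------------------------------------------


@lru_cache(maxsize=8)
def _gammatone_bank(fs: int, n_channels: int, fmin: float, fmax: float):
    centers = np.geomspace(fmin, fmax, n_channels)
    kernels = []
    for fc in centers:
        b, _ = signal.gammatone(fc, "fir", fs=fs)
        kernels.append(np.asarray(b, float))
    return centers, kernels


def compute_auditory_spectrogram(
    w: Waveform,
    n_channels: int = 128,
    fmin: float = DEFAULT_FMIN_HZ,
    fmax: float = DEFAULT_FMAX_HZ,
    frame_rate_hz: float = DEFAULT_FRAME_RATE_HZ,
) -> AuditorySpectrogram:
    """Filter, envelope-extract, compress, and frame a waveform.

    Each channel is a 4th-order gammatone bandpass (a standard model of
    peripheral auditory filtering); the channel envelope is the Hilbert
    magnitude, compressed by a cube root, and averaged over 10 ms frames.
    """
    if w.samples.size == 0:
        raise InvalidInputError("empty waveform")
    fs = int(w.sample_rate_hz)
    if fmax >= fs / 2:
        raise InvalidConfigError("fmax must be below the Nyquist frequency")
    if n_channels < 1:
        raise InvalidConfigError("need at least one channel")

    hop_f = fs / frame_rate_hz
    hop = int(round(hop_f))
    x = w.samples
    if abs(hop_f - hop) > 1e-9:
        # resample so an integer number of samples falls in each frame
        target_fs = int(round(hop_f)) * int(frame_rate_hz)
        warnings.warn(
            f"sample rate {fs} not divisible by frame rate; resampling to {target_fs}"
        )
        x = signal.resample_poly(x, target_fs, fs)
        fs = target_fs
        hop = fs // int(frame_rate_hz)

    n_frames = x.size // hop
    if n_frames == 0:
        raise InvalidInputError("waveform shorter than one analysis frame")
    x = x[: n_frames * hop]

    centers, kernels = _gammatone_bank(fs, n_channels, float(fmin), float(fmax))
    vals = np.empty((n_channels, n_frames))
    for i, b in enumerate(kernels):
        y = signal.fftconvolve(x, b, mode="full")[: x.size]
        env = np.abs(signal.hilbert(y))
        comp = np.cbrt(env)
        vals[i] = comp.reshape(n_frames, hop).mean(axis=1)
    return AuditorySpectrogram(vals, centers, frame_rate_hz)


def downsample_spectrogram(s: AuditorySpectrogram, n_out: int = 32) -> AuditorySpectrogram:
    """Average non-overlapping groups of adjacent frequency channels.

    Group centres are geometric means, which keeps the output axis exactly
    log-spaced.
    """
    if n_out < 1 or s.n_freq % n_out != 0:
        raise InvalidConfigError(
            f"n_freq={s.n_freq} is not divisible by n_out={n_out}"
        )
    g = s.n_freq // n_out
    vals = s.values.reshape(n_out, g, s.n_frames).mean(axis=1)
    centers = np.exp(np.log(s.freq_centers_hz).reshape(n_out, g).mean(axis=1))
    return AuditorySpectrogram(vals, centers, s.frame_rate_hz)


# ---------------------------------------------------------------------------
# Modulation filterbank
# ---------------------------------------------------------------------------


@lru_cache(maxsize=64)
def _temporal_kernel(rate: float, frame_rate: float) -> np.ndarray:
    """Causal gamma-windowed complex exponential selective for one rate.

    The kernel is analytic in time (positive temporal frequencies only) and
    has its mean removed so that a temporally constant input produces zero
    output; the passband peak gain is normalized to 1.
    """
    t_max = 4.0 / rate
    t = np.arange(0.0, t_max, 1.0 / frame_rate)
    env = (rate * t) ** 2 * np.exp(-3.5 * rate * t)
    k = env * np.exp(2j * np.pi * rate * t)
    k = k - k.mean()  # exact DC rejection
    nfft = max(1024, 4 * k.size)
    gain = np.abs(np.fft.fft(k, nfft)).max()
    return k / gain


@lru_cache(maxsize=64)
def _spectral_kernel(scale: float, dx_oct: float) -> np.ndarray:
    """Complex Gabor along the log-frequency axis for one spectral scale.

    ``dx_oct`` is the channel spacing in octaves. The kernel is analytic in
    spectral frequency (responds to one sign of spectral modulation); the
    conjugate kernel responds to the opposite sign.
    """
    sigma = 0.6 / scale  # octaves
    half = max(2, int(np.ceil(3.0 * sigma / dx_oct)))
    x = np.arange(-half, half + 1) * dx_oct
    env = np.exp(-0.5 * (x / sigma) ** 2)
    k = env * np.exp(2j * np.pi * scale * x)
    nfft = max(1024, 4 * k.size)
    gain = np.abs(np.fft.fft(k, nfft)).max()
    return k / gain


def _temporal_filter(values: np.ndarray, kt: np.ndarray) -> np.ndarray:
    """Causal temporal convolution with initial-value padding.

    The signal is extended to the left at its initial frame so that a
    temporally constant input yields exactly zero output (the kernels are
    zero-mean); onset transients then reflect real envelope changes only.
    """
    T = values.shape[1]
    pad = np.repeat(values[:, :1], kt.size - 1, axis=1)
    padded = np.concatenate([pad, values], axis=1)
    return signal.fftconvolve(padded, kt[None, :], mode="full")[:, kt.size - 1:
                                                                kt.size - 1 + T]


def _modulation_transform(
    values: np.ndarray,
    dx_oct: float,
    frame_rate: float,
    rates=DEFAULT_RATES_HZ,
    scales=DEFAULT_SCALES_CYC_PER_OCT,
):
    """Complex filterbank output for every (scale, signed rate) pair.

    Yields ``(scale, signed_rate, Z)`` with ``Z`` complex of the input shape.
    Negative rates (upward sweeps) use the conjugate spectral kernel.
    """
    for rate in rates:
        kt = _temporal_kernel(float(rate), float(frame_rate))
        y = _temporal_filter(values, kt)
        for scale in scales:
            ks = _spectral_kernel(float(scale), float(dx_oct))
            z_down = signal.fftconvolve(y, ks[:, None], mode="same")
            z_up = signal.fftconvolve(y, np.conj(ks)[:, None], mode="same")
            yield scale, -rate, z_up
            yield scale, rate, z_down


def _signed_rates(rates) -> np.ndarray:
    r = np.asarray(rates, float)
    return np.concatenate([-r[::-1], r])


def compute_modulation_representation(
    s: AuditorySpectrogram,
    rates=DEFAULT_RATES_HZ,
    scales=DEFAULT_SCALES_CYC_PER_OCT,
    reduced_form: str = "full",
    n_freq_out: int = 32,
) -> ModulationRepresentation:
    """2-D complex wavelet analysis of the spectrogram, magnitude output.

    ``full`` keeps all four axes (the frequency axis is averaged down to
    ``n_freq_out`` channels when divisible); ``rate_scale`` averages the
    complex output over frequency before taking the magnitude; ``rate_only``
    applies pure temporal filters (unsigned rates) and averages the channel
    magnitudes over frequency.
    """
    if reduced_form not in ("full", "rate_scale", "rate_only"):
        raise InvalidConfigError(f"unknown reduced form {reduced_form!r}")
    if reduced_form in ("full", "rate_scale") and s.n_freq < 2:
        raise InvalidInputError("need >= 2 frequency channels for spectral analysis")

    rates = tuple(float(r) for r in rates)
    scales = tuple(float(c) for c in scales)
    T = s.n_frames
    fr = s.frame_rate_hz

    if reduced_form == "rate_only":
        vals = np.empty((len(rates), T))
        for i, rate in enumerate(rates):
            kt = _temporal_kernel(rate, fr)
            y = _temporal_filter(s.values, kt)
            vals[i] = np.abs(y).mean(axis=0)
        return ModulationRepresentation(
            vals, np.asarray(rates), np.asarray(scales), "rate_only", fr
        )

    dx = s.channel_spacing_octaves
    signed = _signed_rates(rates)
    n_s, n_r = len(scales), signed.size
    r_index = {r: i for i, r in enumerate(signed)}
    s_index = {c: i for i, c in enumerate(scales)}

    if reduced_form == "rate_scale":
        vals = np.empty((n_s, n_r, T))
        for scale, srate, z in _modulation_transform(s.values, dx, fr, rates, scales):
            vals[s_index[scale], r_index[srate]] = np.abs(z.mean(axis=0))
        return ModulationRepresentation(
            vals, signed, np.asarray(scales), "rate_scale", fr
        )

    # full form
    if s.n_freq > n_freq_out and s.n_freq % n_freq_out == 0:
        g = s.n_freq // n_freq_out
        freq_out = np.exp(np.log(s.freq_centers_hz).reshape(n_freq_out, g).mean(axis=1))

        def reduce_freq(m):
            return m.reshape(n_freq_out, g, T).mean(axis=1)

    else:
        freq_out = s.freq_centers_hz

        def reduce_freq(m):
            return m

    vals = np.empty((n_s, n_r, freq_out.size, T))
    for scale, srate, z in _modulation_transform(s.values, dx, fr, rates, scales):
        vals[s_index[scale], r_index[srate]] = reduce_freq(np.abs(z))
    return ModulationRepresentation(
        vals, signed, np.asarray(scales), "full", fr, freq_centers_hz=freq_out
    )


# ---------------------------------------------------------------------------
# Inversions
# ---------------------------------------------------------------------------


def _transfer_bank(n_freq: int, dx_oct: float, frame_rate: float, rates, scales, n_t: int):
    """2-D DFT-domain transfer functions of the full filterbank.

    Returns an array ``H[k, n_freq_fft, n_t]`` ordered to match the (scale,
    signed rate) axes of the full representation.
    """
    signed = _signed_rates(rates)
    max_klen = max(_spectral_kernel(float(c), float(dx_oct)).size for c in scales)
    nf = int(2 ** np.ceil(np.log2(n_freq + max_klen)))
    H = np.empty((len(scales) * signed.size, nf, n_t), dtype=complex)
    for si, scale in enumerate(scales):
        ks = _spectral_kernel(float(scale), float(dx_oct))
        half = (ks.size - 1) // 2
        for ri, srate in enumerate(signed):
            kt = _temporal_kernel(abs(float(srate)), float(frame_rate))
            kern = ks if srate > 0 else np.conj(ks)
            # centre the spectral kernel at index 0 (circular convolution)
            kf = np.zeros(nf, dtype=complex)
            kf[: half + 1] = kern[half:]
            kf[-half:] = kern[:half]
            Hf = np.fft.fft(kf)
            Ht = np.fft.fft(kt, n_t)
            H[si * signed.size + ri] = Hf[:, None] * Ht[None, :]
    return H, nf


def invert_modulation_to_spectrogram(
    m: ModulationRepresentation,
    n_init: int = 100,
    seed: int | None = None,
    max_iter: int = 200,
    tol: float = 1e-4,
) -> AuditorySpectrogram:
    """Recover a spectrogram from magnitude-only modulation energy.

    Iterative projection: starting from a random nonnegative spectrogram,
    alternately (i) apply the complex filterbank, substitute the target
    magnitudes while keeping the current phases, and (ii) invert by
    regularized filterbank summation, clipping to nonnegative values. The
    returned spectrogram is the average over ``n_init`` random
    initializations and is deterministic given ``seed``. Recovery is
    approximate by nature of the phase-retrieval problem.
    """
    if m.reduced_form != "full":
        raise InvalidInputError("inversion requires the full modulation form")
    if m.freq_centers_hz is None:
        raise InvalidInputError("full form must carry its frequency axis")
    target = m.values  # (S, R, F, T)
    n_sc, n_rt, n_freq, T = target.shape
    rates = tuple(float(r) for r in m.rates_hz[m.rates_hz > 0])
    scales = tuple(float(c) for c in m.scales_cyc_per_oct)
    dx = float(
        np.log2(m.freq_centers_hz[-1] / m.freq_centers_hz[0]) / (n_freq - 1)
    )
    fr = m.frame_rate_hz

    longest = max(_temporal_kernel(r, fr).size for r in rates)
    n_t = int(2 ** np.ceil(np.log2(T + longest)))
    H, nf = _transfer_bank(n_freq, dx, fr, rates, scales, n_t)
    M = target.reshape(n_sc * n_rt, n_freq, T)
    denom = np.sum(np.abs(H) ** 2, axis=0)
    denom = denom + 1e-3 * denom.max()

    if not np.any(M > 0):
        return AuditorySpectrogram(np.zeros((n_freq, T)), m.freq_centers_hz, fr)

    rng = np.random.default_rng(seed)
    scale0 = M.mean()
    acc = np.zeros((n_freq, T))
    for _ in range(n_init):
        S = scale0 * rng.random((n_freq, T))
        prev = None
        converged = False
        for _ in range(max_iter):
            Sh = np.fft.fft2(S, s=(nf, n_t))
            Z = np.fft.ifft2(H * Sh[None])[:, :n_freq, :T]
            mag = np.abs(Z)
            Zp = np.where(mag > 1e-12, M * Z / np.maximum(mag, 1e-12), M)
            num = np.sum(np.conj(H) * np.fft.fft2(Zp, s=(nf, n_t)), axis=0)
            S_new = np.real(np.fft.ifft2(num / denom))[:n_freq, :T]
            np.clip(S_new, 0.0, None, out=S_new)
            if prev is not None and prev.std() > 0 and S_new.std() > 0:
                c = np.corrcoef(prev.ravel(), S_new.ravel())[0, 1]
                if 1.0 - c < tol:
                    S = S_new
                    converged = True
                    break
            prev = S_new
            S = S_new
        if not converged and max_iter > 1:
            warnings.warn("modulation inversion did not converge; using best iterate")
        acc += S
    return AuditorySpectrogram(acc / n_init, m.freq_centers_hz, fr)


def invert_spectrogram_to_waveform(
    s: AuditorySpectrogram,
    n_iter: int = 30,
    seed: int | None = None,
    sample_rate_hz: int = 16000,
) -> Waveform:
    """Estimate a waveform whose spectrogram matches ``s``.

    Griffin-Lim-style alternating projections over the gammatone filterbank:
    starting from seeded white noise, each iteration filters the current
    waveform into channels, rescales each channel's Hilbert envelope to the
    target envelope (un-compressed), and resynthesizes by filterbank
    summation. Deterministic given ``seed``.
    """
    fs = int(sample_rate_hz)
    hop = int(round(fs / s.frame_rate_hz))
    n_samples = s.n_frames * hop
    if n_samples == 0:
        raise InvalidInputError("empty spectrogram")

    # undo the cube-root compression, then upsample the frame envelope
    env_lin = s.values**3
    t_frames = (np.arange(s.n_frames) + 0.5) * hop
    t_samp = np.arange(n_samples)
    targets = np.empty((s.n_freq, n_samples))
    for i in range(s.n_freq):
        targets[i] = np.interp(t_samp, t_frames, env_lin[i])

    if not np.any(targets > 0):
        return Waveform(np.zeros(n_samples), fs)

    _, kernels = _gammatone_bank(fs, s.n_freq, float(s.freq_centers_hz[0]),
                                 float(s.freq_centers_hz[-1]))
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n_samples)
    x /= max(np.std(x), 1e-12)
    for _ in range(n_iter):
        acc = np.zeros(n_samples)
        for i, b in enumerate(kernels):
            y = signal.fftconvolve(x, b, mode="full")[:n_samples]
            a = signal.hilbert(y)
            env = np.abs(a)
            acc += np.real(a) * targets[i] / (env + 1e-8 * env.max() + 1e-30)
        x = acc
        sd = np.std(x)
        if sd > 0:
            x = x / sd
    # final amplitude scale: match overall target envelope energy
    scale = np.sqrt(np.mean(targets**2))
    return Waveform(x * scale, fs)
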