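"""Preprocessing of multichannel cortical field potentials.

Raw recordings are re-referenced to the common average of the good channels,
band-pass filtered (high gamma, 70-150 Hz, by default), converted to
band power via the squared Hilbert envelope, resampled to the 100 Hz stimulus
frame rate, and z-scored per electrode. A multiband variant produces one
response matrix per 10 Hz band from 1-300 Hz for band-resolved decoding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .exceptions import InvalidConfigError, InvalidInputError

__all__ = [
    "RawRecording",
    "NeuralResponseMatrix",
    "common_average_reference",
    "extract_band_power",
    "multiband_power",
    "align_trials",
    "zscore_columns",
]

log = logging.getLogger(__name__)

DEFAULT_FRAME_RATE_HZ = 100.0
HIGH_GAMMA_BAND = (70.0, 150.0)


@dataclass
class RawRecording:
    """Raw electrode-by-time field potential with sampling metadata."""

    signal: np.ndarray  # [n_electrodes, n_samples]
    sample_rate_hz: float
    bad_channels: frozenset = field(default_factory=frozenset)
    electrode_labels: list | None = None

    def __post_init__(self):
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=float))
        if not np.all(np.isfinite(self.signal)):
            raise InvalidInputError("recording contains non-finite values")
        self.bad_channels = frozenset(int(c) for c in self.bad_channels)
        n = self.signal.shape[0]
        if any(c < 0 or c >= n for c in self.bad_channels):
            raise InvalidInputError("bad channel index outside electrode range")
        if self.electrode_labels is None:
            self.electrode_labels = [f"e{i}" for i in range(n)]

    @property
    def n_electrodes(self) -> int:
        return self.signal.shape[0]

    @property
    def good_channels(self) -> np.ndarray:
        return np.array(
            [i for i in range(self.n_electrodes) if i not in self.bad_channels]
        )


@dataclass
class NeuralResponseMatrix:
    """z-scored band power per electrode at the stimulus frame rate.

    ``values`` has shape ``[n_frames, n_electrodes]``. ``trial_index`` is an
    optional per-frame trial id (int array, -1 outside trials).
    """

    values: np.ndarray
    frame_rate_hz: float = DEFAULT_FRAME_RATE_HZ
    band_hz: tuple | None = None
    standardized: bool = False
    trial_index: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.trial_index is not None:
            self.trial_index = np.asarray(self.trial_index, dtype=int)
            if self.trial_index.size != self.values.shape[0]:
                raise InvalidInputError("trial_index length must match frames")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_electrodes(self) -> int:
        return self.values.shape[1]

    def trial_segments(self):
        """Contiguous (start, stop) frame ranges per trial id, in order."""
        if self.trial_index is None:
            return [(0, self.n_frames)]
        segs = []
        ids = self.trial_index
        for tid in pd.unique(ids[ids >= 0]):
            idx = np.flatnonzero(ids == tid)
            segs.append((int(idx[0]), int(idx[-1]) + 1))
        return segs


def zscore_columns(values: np.ndarray) -> np.ndarray:
    """Column-wise standardization to zero mean, unit SD (ddof=0)."""
    mu = values.mean(axis=0, keepdims=True)
    sd = values.std(axis=0, keepdims=True)
    sd = np.where(sd > 0, sd, 1.0)
    return (values - mu) / sd


def common_average_reference(rec: RawRecording) -> RawRecording:
    """Subtract the mean of the good channels from every good channel.

    Bad channels do not contribute to the reference and are passed through
    unchanged (still flagged bad).
    """
    good = rec.good_channels
    if good.size < 2:
        raise InvalidInputError("common average reference needs >= 2 good channels")
    ref = rec.signal[good].mean(axis=0)
    out = rec.signal.copy()
    out[good] -= ref
    return RawRecording(out, rec.sample_rate_hz, rec.bad_channels,
                        list(rec.electrode_labels))


def _bandpass_zero_phase(x: np.ndarray, lo: float, hi: float, fs: float) -> np.ndarray:
    """Zero-phase FIR bandpass (Kaiser design, >= 60 dB stopband)."""
    width = max(2.0, 0.3 * lo)
    numtaps, beta = signal.kaiserord(60.0, width / (0.5 * fs))
    numtaps |= 1  # odd length for a type-I filter
    max_taps = x.shape[-1] // 3 - 2  # filtfilt needs len(x) > 3 * ntaps
    if numtaps > max_taps:
        numtaps = max(3, max_taps | 1)
    b = signal.firwin(numtaps, [lo, hi], pass_zero=False, fs=fs,
                      window=("kaiser", beta))
    log.debug("bandpass %g-%g Hz, %d taps", lo, hi, numtaps)
    return signal.filtfilt(b, [1.0], x, axis=-1)


def _resample_to_frames(x: np.ndarray, fs: float, frame_rate: float) -> np.ndarray:
    from fractions import Fraction

    frac = Fraction(frame_rate / fs).limit_denominator(10000)
    return signal.resample_poly(x, frac.numerator, frac.denominator, axis=-1)


def extract_band_power(
    rec: RawRecording,
    band: tuple = HIGH_GAMMA_BAND,
    frame_rate_hz: float = DEFAULT_FRAME_RATE_HZ,
    power: bool = True,
    standardize: bool = True,
) -> NeuralResponseMatrix:
    """Band-pass -> analytic envelope (power) -> 100 Hz frames -> z-score.

    ``power=False`` switches to the envelope amplitude instead of its square.
    Standardization uses the whole recording as the window.
    """
    lo, hi = float(band[0]), float(band[1])
    nyq = rec.sample_rate_hz / 2.0
    if not (0 < lo < hi < nyq):
        raise InvalidConfigError(f"band {band} outside (0, Nyquist={nyq:g})")
    y = _bandpass_zero_phase(rec.signal, lo, hi, rec.sample_rate_hz)
    env = np.abs(signal.hilbert(y, axis=-1))
    feat = env**2 if power else env
    frames = _resample_to_frames(feat, rec.sample_rate_hz, frame_rate_hz)
    values = frames.T  # [n_frames, n_electrodes]
    if standardize:
        values = zscore_columns(values)
    return NeuralResponseMatrix(
        values, frame_rate_hz, band_hz=(lo, hi), standardized=standardize
    )


def multiband_power(
    rec: RawRecording,
    lo: float = 1.0,
    hi: float = 300.0,
    width: float = 10.0,
    frame_rate_hz: float = DEFAULT_FRAME_RATE_HZ,
) -> list:
    """One response matrix per band of ``width`` Hz covering [lo, hi].

    The default 1-300 Hz range with 10 Hz bands yields 30 bands (the range
    is counted with inclusive edges; the last band is clipped at ``hi``).
    """
    span = hi - lo
    if span % width != 0 and (span + 1) % width != 0:
        raise InvalidConfigError("band range must be divisible by the band width")
    n_bands = int(np.ceil(span / width))
    out = []
    for i in range(n_bands):
        b_lo = lo + i * width
        b_hi = min(b_lo + width, hi)
        out.append(extract_band_power(rec, (b_lo, b_hi), frame_rate_hz))
    return out


def align_trials(
    resp: NeuralResponseMatrix,
    events: pd.DataFrame,
    stim_frames,
) -> NeuralResponseMatrix:
    """Segment a continuous response into frame-aligned trials.

    ``events`` must have columns ``trial_id`` and ``onset_s``; ``stim_frames``
    is the per-trial frame count (scalar or sequence aligned with the table).
    The output concatenates trials in table order with a matching
    ``trial_index``.
    """
    fr = resp.frame_rate_hz
    n = len(events)
    frames = np.broadcast_to(np.asarray(stim_frames, dtype=int), (n,)) \
        if np.ndim(stim_frames) else np.full(n, int(stim_frames))
    onsets = np.round(events["onset_s"].to_numpy() * fr).astype(int)
    ends = onsets + frames

    order = np.argsort(onsets, kind="stable")
    for a, b in zip(order[:-1], order[1:]):
        if ends[a] > onsets[b]:
            raise InvalidInputError(
                f"trials {events['trial_id'].iloc[a]!r} and "
                f"{events['trial_id'].iloc[b]!r} overlap"
            )

    chunks, index = [], []
    for i in range(n):
        if onsets[i] < 0 or ends[i] > resp.n_frames:
            raise InvalidInputError(
                f"trial {events['trial_id'].iloc[i]!r} lies outside the recording"
            )
        chunks.append(resp.values[onsets[i]:ends[i]])
        index.append(np.full(frames[i], i))
    return NeuralResponseMatrix(
        np.vstack(chunks),
        fr,
        band_hz=resp.band_hz,
        standardized=resp.standardized,
        trial_index=np.concatenate(index),
    )
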