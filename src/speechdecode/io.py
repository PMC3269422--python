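"""Reading and writing the pipeline's file formats.

Waveforms are PCM WAV (mono, resampled to 16 kHz with a warning when
needed); representations, recordings, and fitted models are HDF5 with named
axes stored as attributes; trial tables are CSV.
"""

from __future__ import annotations

import json
import warnings

import h5py
import numpy as np
import pandas as pd
from scipy import signal
from scipy.io import wavfile

from .audio_frontend import AuditorySpectrogram, ModulationRepresentation, Waveform
from .decoder import ReconstructionModel
from .encoder import StrfModel, TuningCurve
from .exceptions import InvalidInputError
from .neural_preproc import NeuralResponseMatrix, RawRecording
from . import stats as rstats

__all__ = [
    "read_wav",
    "write_wav",
    "save_spectrogram",
    "load_spectrogram",
    "save_modulation",
    "load_modulation",
    "save_response",
    "load_response",
    "load_recording",
    "load_trial_table",
    "save_reconstruction_model",
    "load_reconstruction_model",
    "save_strf",
    "load_strf",
    "tuning_curve_to_csv",
]

TARGET_FS = 16000


def read_wav(path, target_fs: int = TARGET_FS) -> Waveform:
    fs, data = wavfile.read(path)
    was_int = np.issubdtype(data.dtype, np.integer)
    data = np.asarray(data, dtype=float)
    if data.ndim == 2:
        warnings.warn("multichannel WAV averaged to mono")
        data = data.mean(axis=1)
    if was_int:
        data = data / 32768.0
    if fs != target_fs:
        warnings.warn(f"resampling WAV from {fs} to {target_fs} Hz")
        data = signal.resample_poly(data, target_fs, fs)
        fs = target_fs
    return Waveform(data, fs)


def write_wav(path, w: Waveform) -> None:
    x = w.samples
    peak = np.max(np.abs(x)) or 1.0
    wavfile.write(path, int(w.sample_rate_hz),
                  (x / peak * 32000).astype(np.int16))


def save_spectrogram(path, s: AuditorySpectrogram) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("values", data=s.values)
        d.attrs["axes"] = "frequency,time"
        f.attrs["frame_rate_hz"] = s.frame_rate_hz
        f.create_dataset("freq_centers_hz", data=s.freq_centers_hz)


def load_spectrogram(path) -> AuditorySpectrogram:
    with h5py.File(path, "r") as f:
        return AuditorySpectrogram(
            f["values"][()], f["freq_centers_hz"][()], float(f.attrs["frame_rate_hz"])
        )


def save_modulation(path, m: ModulationRepresentation) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("values", data=m.values)
        d.attrs["axes"] = {
            "full": "scale,rate,frequency,time",
            "rate_scale": "scale,rate,time",
            "rate_only": "rate,time",
        }[m.reduced_form]
        f.attrs["frame_rate_hz"] = m.frame_rate_hz
        f.attrs["reduced_form"] = m.reduced_form
        f.create_dataset("rates_hz", data=m.rates_hz)
        f.create_dataset("scales_cyc_per_oct", data=m.scales_cyc_per_oct)
        if m.freq_centers_hz is not None:
            f.create_dataset("freq_centers_hz", data=m.freq_centers_hz)


def load_modulation(path) -> ModulationRepresentation:
    with h5py.File(path, "r") as f:
        return ModulationRepresentation(
            f["values"][()],
            f["rates_hz"][()],
            f["scales_cyc_per_oct"][()],
            str(f.attrs["reduced_form"]),
            float(f.attrs["frame_rate_hz"]),
            f["freq_centers_hz"][()] if "freq_centers_hz" in f else None,
        )


def save_response(path, r: NeuralResponseMatrix) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=r.values)
        f.attrs["frame_rate_hz"] = r.frame_rate_hz
        f.attrs["standardized"] = r.standardized
        if r.band_hz is not None:
            f.attrs["band_hz"] = list(r.band_hz)
        if r.trial_index is not None:
            f.create_dataset("trial_index", data=r.trial_index)


def load_response(path) -> NeuralResponseMatrix:
    with h5py.File(path, "r") as f:
        return NeuralResponseMatrix(
            f["values"][()],
            float(f.attrs["frame_rate_hz"]),
            band_hz=tuple(f.attrs["band_hz"]) if "band_hz" in f.attrs else None,
            standardized=bool(f.attrs.get("standardized", False)),
            trial_index=f["trial_index"][()] if "trial_index" in f else None,
        )


def load_recording(path) -> RawRecording:
    """Raw recording from HDF5 (``/signal`` + attrs) or delimited text."""
    path = str(path)
    if path.endswith((".h5", ".hdf5")):
        with h5py.File(path, "r") as f:
            sig = f["signal"][()]
            fs = float(f["signal"].attrs.get("sample_rate_hz",
                                             f.attrs.get("sample_rate_hz", 0)))
            if fs <= 0:
                raise InvalidInputError("recording lacks sample_rate_hz metadata")
            bad = frozenset(int(c) for c in f.attrs.get("bad_channels", []))
            labels = [
                l.decode() if isinstance(l, bytes) else str(l)
                for l in f.attrs.get("labels", [])
            ] or None
            return RawRecording(sig, fs, bad, labels)
    df = pd.read_csv(path, sep=None, engine="python")
    if "sample_rate_hz" not in df.columns[0].lower() and df.shape[1] < 2:
        raise InvalidInputError("text recording must be [electrodes x samples]")
    return RawRecording(df.to_numpy().T, 1000.0)


def load_trial_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"trial_id", "label", "onset_s", "offset_s"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidInputError(f"trial table missing columns {sorted(missing)}")
    return df


def save_reconstruction_model(path, m: ReconstructionModel, config: dict | None = None):
    with h5py.File(path, "w") as f:
        d = f.create_dataset("weights", data=m.weights)
        d.attrs["axes"] = "stim_channel,lag,electrode"
        f.attrs["stim_space"] = m.stim_space
        f.attrs["lag_step_s"] = m.lag_step_s
        if m.resample_stats is not None:
            g = f.create_group("resample_stats")
            g.create_dataset("mean", data=m.resample_stats.mean)
            g.create_dataset("se", data=m.resample_stats.se)
            g.create_dataset("t_ratio", data=m.resample_stats.t_ratio)
            g.attrs["n_resamples"] = m.resample_stats.n_resamples
        if config is not None:
            f.attrs["config_json"] = json.dumps(config)


def save_strf(path, m: StrfModel) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("weights", data=m.weights)
        d.attrs["axes"] = "feature,lag"
        f.attrs["space"] = m.space
        f.attrs["frame_rate_hz"] = m.frame_rate_hz
        f.attrs["prediction_r"] = m.prediction_r
        if m.axis_hz is not None:
            f.create_dataset("axis_hz", data=m.axis_hz)
        if m.resampled_weights is not None:
            f.create_dataset("resampled_weights", data=m.resampled_weights)


def load_strf(path) -> StrfModel:
    with h5py.File(path, "r") as f:
        stack = (
            f["resampled_weights"][()] if "resampled_weights" in f else None
        )
        stats = (
            rstats.resample_stats(stack.reshape(stack.shape[0], -1))
            if stack is not None
            else None
        )
        return StrfModel(
            f["weights"][()],
            str(f.attrs["space"]),
            axis_hz=f["axis_hz"][()] if "axis_hz" in f else None,
            frame_rate_hz=float(f.attrs["frame_rate_hz"]),
            prediction_r=float(f.attrs["prediction_r"]),
            resample_stats=stats,
            resampled_weights=stack,
        )


def tuning_curve_to_csv(path, c: TuningCurve) -> None:
    peaks = set(np.round(c.peaks, 6)) if c.peaks else set()
    pd.DataFrame(
        {
            "axis_hz": c.axis_hz,
            "value": c.values,
            "se": c.se if c.se is not None else np.nan,
            "is_peak": [round(a, 6) in peaks for a in c.axis_hz],
        }
    ).to_csv(path, index=False)


def load_reconstruction_model(path) -> ReconstructionModel:
    with h5py.File(path, "r") as f:
        stats = None
        if "resample_stats" in f:
            g = f["resample_stats"]
            stats = rstats.ResampleEstimate(
                g["mean"][()], g["se"][()], g["t_ratio"][()],
                int(g.attrs["n_resamples"]),
            )
        return ReconstructionModel(
            f["weights"][()],
            stim_space=str(f.attrs["stim_space"]),
            lag_step_s=float(f.attrs["lag_step_s"]),
            resample_stats=stats,
        )
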