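"""Per-electrode spectro-temporal receptive field (STRF) encoding models.

The encoding model is the linear map from a stimulus representation
``s(x, t)`` to one electrode's response:

    r(t) = sum_x sum_u h(x, u) s(x, t - u) + e(t)

with 100 causal lags at 10 ms. Supported stimulus spaces are the 32-channel
spectrogram (3,200 parameters), the full modulation representation
(192,000), and the reduced rate-only modulation representation (600).
Fitting uses full-gradient descent with early stopping (dense weights, no
sparsity); tuning curves are read off the fitted filters: excitatory-only
sums over lags for frequency and (nonlinear) rate tuning, and either
modulation filterbank projection or the modulation transfer function
(2-D Fourier modulus) for rate tuning of spectrogram-space STRFs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from . import stats as rstats
from .audio_frontend import (
    DEFAULT_RATES_HZ,
    DEFAULT_SCALES_CYC_PER_OCT,
    _spectral_kernel,
    _temporal_kernel,
)
from .decoder import CvPlan, as_feature_matrix
from .exceptions import InvalidConfigError, InvalidInputError
from .neural_preproc import NeuralResponseMatrix

__all__ = [
    "StrfModel",
    "TuningCurve",
    "GradConfig",
    "SPACE_FEATURES",
    "fit_strf",
    "predict_response",
    "frequency_tuning",
    "rate_tuning",
    "find_tuning_peaks",
    "ensemble_tuning",
    "tuning_spread",
]

log = logging.getLogger(__name__)

N_LAGS_DEFAULT = 100
SPACE_FEATURES = {"spectrogram32": 32, "modulation_full": 1920, "rate_only": 6}


@dataclass
class GradConfig:
    """Gradient-descent hyperparameters (early-stopping regularization)."""

    learning_rate: float | None = None  # None -> 1 / Lipschitz estimate
    max_iter: int = 3000
    patience: int | None = 50
    n_lags: int = N_LAGS_DEFAULT


@dataclass
class StrfModel:
    """Dense encoding filter ``h(x, u)`` for one electrode.

    ``weights`` has shape ``[n_features, n_lags]``. ``axis_hz`` carries the
    feature axis (frequency centres for the spectrogram space, unsigned
    rates for the rate-only space).
    """

    weights: np.ndarray
    space: str
    axis_hz: np.ndarray | None = None
    frame_rate_hz: float = 100.0
    prediction_r: float = np.nan
    resample_stats: rstats.ResampleEstimate | None = None
    resampled_weights: np.ndarray | None = None  # (n_resamples, F, L)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2:
            raise InvalidInputError("STRF weights must be [features, lags]")
        if self.space not in SPACE_FEATURES:
            raise InvalidConfigError(f"unknown STRF space {self.space!r}")

    @property
    def n_parameters(self) -> int:
        return self.weights.size


@dataclass
class TuningCurve:
    """Marginal sensitivity along frequency (Hz) or modulation rate (Hz)."""

    axis_hz: np.ndarray
    values: np.ndarray
    se: np.ndarray | None = None
    peaks: list | None = None
    normalized: bool = False

    def max_normalized(self) -> "TuningCurve":
        peak = self.values.max()
        if peak <= 0:
            return TuningCurve(self.axis_hz, self.values.copy(), self.se,
                               self.peaks, True)
        return TuningCurve(
            self.axis_hz,
            self.values / peak,
            None if self.se is None else self.se / peak,
            self.peaks,
            True,
        )


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def _lagged_stim(S: np.ndarray, segments, n_lags: int):
    """Causal lagged design: row t holds s(x, t-u) for u = 0..L-1."""
    F = S.shape[0]
    blocks, frames = [], []
    for a, b in segments:
        if b - a < n_lags:
            raise InvalidInputError("trial shorter than the lag window")
        w = sliding_window_view(S[:, a:b], n_lags, axis=1)  # (F, T', L)
        w = np.flip(w, axis=2)  # index u: lag into the past
        blocks.append(w.transpose(1, 0, 2).reshape(-1, F * n_lags))
        frames.append(np.arange(a + n_lags - 1, b))
    return np.ascontiguousarray(np.vstack(blocks)), np.concatenate(frames)


def _gradient_descent(Xtr, ytr, Xva, yva, config: GradConfig):
    """Steepest descent on the training MSE with exact line search.

    When a validation set is given, the iterate with the lowest validation
    MSE is returned and iteration stops after ``patience`` consecutive
    non-improving steps (early-stopping regularization). ``learning_rate``
    overrides the line search with a fixed step.
    """
    T, P = Xtr.shape
    w = np.zeros(P)
    use_val = config.patience is not None and Xva is not None and Xva.size
    best_w = w.copy()
    best_mse = np.inf
    stall = 0
    for _ in range(config.max_iter):
        grad = Xtr.T @ (Xtr @ w - ytr) / T
        if config.learning_rate is not None:
            step = config.learning_rate
        else:
            Xg = Xtr @ grad
            curv = (Xg @ Xg) / T
            if curv <= 0:
                break
            step = (grad @ grad) / curv
        w = w - step * grad
        if use_val:
            mse = np.mean((yva - Xva @ w) ** 2)
            if mse < best_mse:
                best_mse = mse
                best_w = w.copy()
                stall = 0
            else:
                stall += 1
                if stall > config.patience:
                    break
    return (best_w if use_val else w)


def _space_axis(space: str, stim_axis) -> np.ndarray | None:
    if stim_axis is not None:
        return np.asarray(stim_axis, float)
    return None


def fit_strf(
    stim,
    resp_channel: np.ndarray,
    plan_or_split,
    config: GradConfig | None = None,
    space: str = "spectrogram32",
    axis_hz=None,
    trial_segments=None,
    n_resamples: int = 20,
) -> StrfModel:
    """Fit a dense STRF by early-stopped gradient descent.

    ``plan_or_split`` is either a single ``(train_trials, val_trials)``
    split, or a :class:`~speechdecode.decoder.CvPlan` in which case the model
    is cross-validated over resamples (20 by default), per-weight resampled
    statistics are attached, and ``prediction_r`` is the Fisher-averaged
    test-set accuracy.
    """
    config = config or GradConfig()
    S = as_feature_matrix(stim)
    y = np.asarray(resp_channel, dtype=float).ravel()
    if S.shape[1] != y.size:
        raise InvalidInputError("stimulus and response frame counts differ")
    if not np.all(np.isfinite(S)) or not np.all(np.isfinite(y)):
        raise InvalidInputError("non-finite values in fitting data")
    segs = trial_segments if trial_segments is not None else [(0, y.size)]
    L = config.n_lags

    def seg_subset(idx):
        return [segs[i] for i in idx]

    if isinstance(plan_or_split, CvPlan):
        plan = plan_or_split
        if plan.n_resamples != n_resamples:
            n_resamples = plan.n_resamples
        parts = plan.partitions(len(segs))
        stack, test_rs = [], []
        for train_idx, val_idx, test_idx in parts:
            Xtr, ftr = _lagged_stim(S, seg_subset(train_idx), L)
            Xva, fva = _lagged_stim(S, seg_subset(val_idx), L)
            w = _gradient_descent(Xtr, y[ftr], Xva, y[fva], config)
            stack.append(w)
            Xte, fte = _lagged_stim(S, seg_subset(test_idx), L)
            pred = Xte @ w
            if pred.std() > 0 and y[fte].std() > 0:
                test_rs.append(np.corrcoef(pred, y[fte])[0, 1])
        stack = np.asarray(stack)
        stats = rstats.resample_stats(stack)
        weights = stats.mean.reshape(S.shape[0], L)
        pred_r = rstats.fisher_mean(test_rs) if test_rs else np.nan
        return StrfModel(
            weights,
            space,
            axis_hz=_space_axis(space, axis_hz),
            prediction_r=pred_r,
            resample_stats=stats,
            resampled_weights=stack.reshape(len(stack), S.shape[0], L),
        )

    train_idx, val_idx = plan_or_split
    Xtr, ftr = _lagged_stim(S, seg_subset(train_idx), L)
    if val_idx is not None and len(val_idx):
        Xva, fva = _lagged_stim(S, seg_subset(val_idx), L)
        w = _gradient_descent(Xtr, y[ftr], Xva, y[fva], config)
    else:
        w = _gradient_descent(Xtr, y[ftr], None, None, config)
    return StrfModel(w.reshape(S.shape[0], L), space,
                     axis_hz=_space_axis(space, axis_hz))


def predict_response(m: StrfModel, stim, observed=None):
    """Convolve the stimulus with the STRF; optionally score against data.

    Returns ``(prediction, r)`` where the prediction is NaN over the first
    ``n_lags - 1`` frames and ``r`` is the Pearson correlation with
    ``observed`` on the valid frames (None if not supplied).
    """
    S = as_feature_matrix(stim)
    if S.shape[0] != m.weights.shape[0]:
        raise InvalidInputError(
            f"stimulus has {S.shape[0]} features, model expects "
            f"{m.weights.shape[0]} ({m.space})"
        )
    L = m.weights.shape[1]
    X, frames = _lagged_stim(S, [(0, S.shape[1])], L)
    pred = np.full(S.shape[1], np.nan)
    pred[frames] = X @ m.weights.ravel()
    r = None
    if observed is not None:
        obs = np.asarray(observed, float).ravel()
        ok = np.isfinite(pred) & np.isfinite(obs)
        if pred[ok].std() > 0 and obs[ok].std() > 0:
            r = float(np.corrcoef(pred[ok], obs[ok])[0, 1])
        else:
            r = np.nan
    return pred, r


# ---------------------------------------------------------------------------
# Tuning curves
# ---------------------------------------------------------------------------


def _excitatory_marginal(weights: np.ndarray) -> np.ndarray:
    """Zero inhibitory weights, then sum over the lag axis."""
    return np.clip(weights, 0.0, None).sum(axis=-1)


def _per_resample_se(m: StrfModel, transform) -> np.ndarray | None:
    if m.resampled_weights is None:
        return None
    curves = np.asarray([transform(w) for w in m.resampled_weights])
    return curves.std(axis=0, ddof=1)


def frequency_tuning(m: StrfModel) -> TuningCurve:
    """Excitatory frequency marginal of a spectrogram-space STRF."""
    if m.space != "spectrogram32":
        raise InvalidInputError("frequency tuning requires a spectrogram32 STRF")
    values = _excitatory_marginal(m.weights)
    se = _per_resample_se(m, _excitatory_marginal)
    return TuningCurve(axis_hz=m.axis_hz, values=values, se=se)


def _filterbank_rate_marginal(weights, dx_oct, frame_rate,
                              rates=DEFAULT_RATES_HZ,
                              scales=DEFAULT_SCALES_CYC_PER_OCT) -> np.ndarray:
    """RMS modulation output per unsigned rate of a (F, L) filter.

    The STRF is filtered by each (rate, scale, sweep-direction) kernel with
    the complete (uncropped) convolution; per-kernel output energy is
    normalized by the kernel energy so rate channels are comparable, then
    averaged over the scale and direction axes.
    """
    from scipy.signal import fftconvolve

    vals = {r: [] for r in rates}
    for r in rates:
        kt = _temporal_kernel(float(r), float(frame_rate))
        e_t = float(np.sum(np.abs(kt) ** 2))
        y = fftconvolve(weights, kt[None, :], mode="full")
        for c in scales:
            ks = _spectral_kernel(float(c), float(dx_oct))
            e_s = float(np.sum(np.abs(ks) ** 2))
            for kern in (ks, np.conj(ks)):
                z = fftconvolve(y, kern[:, None], mode="full")
                vals[r].append(np.sum(np.abs(z) ** 2) / (e_t * e_s))
    return np.sqrt(np.array([np.mean(vals[r]) for r in rates]))


def _mtf_rate_marginal(weights, dx_oct, frame_rate, rates=DEFAULT_RATES_HZ,
                       max_scale: float = 8.0) -> np.ndarray:
    """Rate marginal of the modulation transfer function.

    The MTF is the modulus of the 2-D Fourier transform of the STRF; each
    rate value is the RMS modulus over a half-octave band of temporal
    frequencies (both sweep directions) and spectral frequencies up to
    ``max_scale`` cyc/oct.
    """
    F, L = weights.shape
    nfft_t = max(256, 4 * L)
    nfft_f = max(128, 4 * F)
    mtf2 = np.abs(np.fft.fft2(weights, s=(nfft_f, nfft_t))) ** 2
    omega = np.fft.fftfreq(nfft_f, d=dx_oct)  # cyc/oct
    ft = np.fft.fftfreq(nfft_t, d=1.0 / frame_rate)  # Hz
    keep_f = np.abs(omega) <= max_scale
    out = np.empty(len(rates))
    for i, r in enumerate(rates):
        band = (np.abs(ft) >= r / np.sqrt(2)) & (np.abs(ft) < r * np.sqrt(2))
        out[i] = np.sqrt(mtf2[np.ix_(keep_f, band)].mean())
    return out


def rate_tuning(m: StrfModel, method: str = "nonlinear",
                rates=DEFAULT_RATES_HZ) -> TuningCurve:
    """Temporal modulation rate tuning of an STRF.

    ``nonlinear``: excitatory lag-sum of a rate-only (or full modulation)
    STRF. ``linear_filterbank``: the spectrogram-space STRF is filtered with
    the modulation filterbank and the magnitudes averaged over the
    irrelevant axes. ``linear_mtf``: rate marginal of the STRF's modulation
    transfer function. Signed rates are averaged to the 6 unsigned values.
    """
    rates = tuple(float(r) for r in rates)
    if method == "nonlinear":
        if m.space not in ("rate_only", "modulation_full"):
            raise InvalidInputError("nonlinear rate tuning needs a modulation STRF")
        if m.space == "rate_only":
            values = _excitatory_marginal(m.weights)
            se = _per_resample_se(m, _excitatory_marginal)
            axis = m.axis_hz if m.axis_hz is not None else np.asarray(rates)
            return TuningCurve(axis, values, se)
        # full model: marginalize scale, sign, and frequency
        n_s, n_r = len(DEFAULT_SCALES_CYC_PER_OCT), 2 * len(rates)

        def marginal(w):
            exc = _excitatory_marginal(w)  # sums lags -> (1920,)
            grid = exc.reshape(n_s, n_r, -1).sum(axis=(0, 2))
            # signed rates run [-32..-1, 1..32]; fold onto unsigned ascending
            return 0.5 * (grid[: len(rates)][::-1] + grid[len(rates):])

        values = marginal(m.weights)
        se = _per_resample_se(m, marginal)
        return TuningCurve(np.asarray(rates), values, se)

    if m.space != "spectrogram32":
        raise InvalidInputError(f"{method} rate tuning needs a spectrogram32 STRF")
    if m.axis_hz is None:
        raise InvalidInputError("spectrogram STRF lacks its frequency axis")
    dx = float(np.log2(m.axis_hz[-1] / m.axis_hz[0]) / (m.axis_hz.size - 1))
    if method == "linear_filterbank":
        f = lambda w: _filterbank_rate_marginal(w, dx, m.frame_rate_hz, rates)
    elif method == "linear_mtf":
        f = lambda w: _mtf_rate_marginal(w, dx, m.frame_rate_hz, rates)
    else:
        raise InvalidConfigError(f"unknown rate tuning method {method!r}")
    return TuningCurve(np.asarray(rates), f(m.weights), _per_resample_se(m, f))


# ---------------------------------------------------------------------------
# Peaks and ensembles
# ---------------------------------------------------------------------------


def find_tuning_peaks(
    c: TuningCurve,
    t_stats=None,
    t_threshold: float = 2.0,
    min_separation_oct: float = 0.5,
):
    """Significant, separated local maxima of a tuning curve.

    A peak is a local maximum whose t-statistic (value / resampled SE, or
    supplied directly) exceeds ``t_threshold``; maxima closer than half an
    octave are merged keeping the larger (exact ties keep the lower
    frequency). Returns peak axis positions in Hz.
    """
    v = np.asarray(c.values, float)
    if t_stats is None:
        if c.se is None:
            raise InvalidInputError("peak detection needs t-statistics or SEs")
        with np.errstate(divide="ignore", invalid="ignore"):
            t_stats = np.where(c.se > 0, v / c.se, np.inf * np.sign(v))
    t_stats = np.asarray(t_stats, float)

    n = v.size
    is_max = np.zeros(n, dtype=bool)
    for i in range(n):
        left = v[i - 1] if i > 0 else -np.inf
        right = v[i + 1] if i < n - 1 else -np.inf
        is_max[i] = v[i] > left and v[i] >= right and v[i] > 0
    cand = [i for i in np.flatnonzero(is_max) if t_stats[i] > t_threshold]

    # merge within half an octave, larger amplitude wins; ties -> lower freq
    cand.sort(key=lambda i: (-v[i], c.axis_hz[i]))
    kept = []
    for i in cand:
        if all(
            abs(np.log2(c.axis_hz[i] / c.axis_hz[j])) > min_separation_oct
            for j in kept
        ):
            kept.append(i)
    kept.sort()
    return [float(c.axis_hz[i]) for i in kept]


def ensemble_tuning(
    models,
    min_r: float = 0.1,
    kind: str = "frequency",
    rate_method: str = "nonlinear",
):
    """Max-normalized average tuning curve across predictive sites.

    Sites with forward prediction accuracy ``r <= min_r`` are excluded.
    Returns ``(mean_curve, peak_histogram)`` where the histogram counts
    per-site peak locations on the curve axis.
    """
    curves, peaks_all = [], []
    for m in models:
        if not np.isfinite(m.prediction_r) or m.prediction_r <= min_r:
            continue
        c = frequency_tuning(m) if kind == "frequency" else rate_tuning(m, rate_method)
        curves.append(c.max_normalized())
        if c.se is not None:
            peaks_all.extend(find_tuning_peaks(c))
    if not curves:
        raise InvalidInputError("no sites pass the prediction-accuracy filter")
    axis = curves[0].axis_hz
    stack = np.asarray([c.values for c in curves])
    mean_curve = TuningCurve(
        axis,
        stack.mean(axis=0),
        se=stack.std(axis=0, ddof=1) / np.sqrt(len(curves))
        if len(curves) > 1
        else None,
        normalized=True,
    )
    hist = np.zeros(axis.size)
    for p in peaks_all:
        hist[int(np.argmin(np.abs(np.log2(axis / p))))] += 1
    return mean_curve, hist


def tuning_spread(models, n_bins: int = 32,
                  fmin: float = 180.0, fmax: float = 7000.0) -> float:
    """Fraction of frequency bins covered by at least one site's peak."""
    edges = np.geomspace(fmin, fmax, n_bins + 1)
    covered = np.zeros(n_bins, dtype=bool)
    for m in models:
        curve = frequency_tuning(m)
        for p in find_tuning_peaks(curve):
            b = int(np.clip(np.searchsorted(edges, p, side="right") - 1, 0,
                            n_bins - 1))
            covered[b] = True
    return float(covered.mean())
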