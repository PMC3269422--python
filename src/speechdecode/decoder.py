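"""Linear stimulus reconstruction from population responses.

The reconstruction model maps the z-scored response matrix ``R(t, n)`` onto a
stimulus representation ``S(f, t)`` through per-channel filters over
electrodes and temporal lags:

    S_hat(f, t) = sum_n sum_tau g(tau, f, n) R(t + tau, n)

Each stimulus channel is estimated independently with 100 lags at 10 ms
(the decoder looks forward in time from the stimulus frame: the stimulus
precedes the response it is decoded from). Fitting uses greedy coordinate
descent with early stopping on a validation set, which yields sparse weight
vectors; model evaluation uses Monte Carlo cross-validation over trials with
resampled parameter statistics (mean, SE, t-ratio).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats as sps

from . import stats as rstats
from .audio_frontend import (
    AuditorySpectrogram,
    ModulationRepresentation,
    compute_modulation_representation,
)
from .exceptions import InvalidConfigError, InvalidInputError
from .neural_preproc import NeuralResponseMatrix

__all__ = [
    "FitConfig",
    "CvPlan",
    "ReconstructionModel",
    "AccuracyReport",
    "fit_reconstruction",
    "predict_stimulus",
    "run_monte_carlo_cv",
    "evaluate_accuracy",
    "rate_resolved_accuracy",
    "rate_accuracy_from_rate_scale",
    "informative_electrodes",
    "electrode_count_curve",
    "coordinate_descent",
    "as_feature_matrix",
]

log = logging.getLogger(__name__)

N_LAGS_DEFAULT = 100
LAG_STEP_S = 0.01


@dataclass
class FitConfig:
    """Hyperparameters of the early-stopped coordinate descent.

    ``step_scale`` is the fixed step expressed as a fraction of the
    target-to-feature SD ratio (boosting-style forward stagewise updates);
    ``patience`` counts consecutive iterations without validation
    improvement before stopping (``None`` disables early stopping and the
    final iterate is returned).
    """

    step_scale: float = 1e-3
    max_iter: int = 100_000
    patience: int | None = 50
    n_lags: int = N_LAGS_DEFAULT


@dataclass
class CvPlan:
    """Monte Carlo cross-validation plan partitioning whole trials."""

    n_resamples: int = 10
    fractions: tuple = (0.8, 0.1, 0.1)
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise InvalidConfigError("train/val/test fractions must sum to 1")

    def partitions(self, n_trials: int):
        """Deterministic (train, val, test) trial-index splits.

        Identical for any model fitted under the same plan, which is what
        makes paired comparisons between stimulus spaces valid.
        """
        n_test = max(1, int(round(self.fractions[2] * n_trials)))
        n_val = max(1, int(round(self.fractions[1] * n_trials)))
        n_train = n_trials - n_test - n_val
        if n_train < 1:
            raise InvalidConfigError("too few trials to form non-empty splits")
        rng = np.random.default_rng(self.seed)
        parts = []
        for _ in range(self.n_resamples):
            perm = rng.permutation(n_trials)
            parts.append(
                (
                    np.sort(perm[:n_train]),
                    np.sort(perm[n_train:n_train + n_val]),
                    np.sort(perm[n_train + n_val:]),
                )
            )
        return parts


@dataclass
class ReconstructionModel:
    """Per-channel decoding filters ``g`` over lags and electrodes.

    ``weights`` has shape ``[n_stim_channels, n_lags, n_electrodes]``. Zero
    weights are valid and expected: the fitting algorithm performs variable
    selection implicitly.
    """

    weights: np.ndarray
    stim_space: str = "spectrogram32"
    lag_step_s: float = LAG_STEP_S
    resample_stats: rstats.ResampleEstimate | None = None

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 3:
            raise InvalidInputError("weights must be [channels, lags, electrodes]")

    @property
    def n_channels(self) -> int:
        return self.weights.shape[0]

    @property
    def n_lags(self) -> int:
        return self.weights.shape[1]

    @property
    def n_electrodes(self) -> int:
        return self.weights.shape[2]


@dataclass
class AccuracyReport:
    """Per-channel Pearson accuracy with Fisher-z aggregated mean."""

    per_channel_r: np.ndarray
    mean_r: float
    n_test_frames: int
    per_rate_r: np.ndarray | None = None
    n_excluded_channels: int = 0


def as_feature_matrix(stim) -> np.ndarray:
    """Coerce a stimulus representation to a [n_channels, n_frames] array."""
    if isinstance(stim, AuditorySpectrogram):
        return stim.values
    if isinstance(stim, ModulationRepresentation):
        return stim.flatten_channels()
    arr = np.asarray(stim, dtype=float)
    if arr.ndim != 2:
        raise InvalidInputError("stimulus must be 2-D [channels, frames]")
    return arr


# ---------------------------------------------------------------------------
# Design matrices
# ---------------------------------------------------------------------------


def _segments(resp: NeuralResponseMatrix, trial_subset=None):
    segs = resp.trial_segments()
    if trial_subset is None:
        return segs
    return [segs[i] for i in trial_subset]


def _lagged_design(resp_values: np.ndarray, segments, n_lags: int):
    """Stack per-trial lagged windows of the response.

    Returns ``(X, frame_idx)`` where ``X[t, n * n_lags + tau] =
    R[frame_idx[t] + tau, n]``. Windows never cross trial boundaries.
    """
    blocks, frames = [], []
    n_elec = resp_values.shape[1]
    for a, b in segments:
        if b - a < n_lags:
            raise InvalidInputError(
                f"trial of {b - a} frames is shorter than {n_lags} lags"
            )
        w = sliding_window_view(resp_values[a:b], n_lags, axis=0)  # (T', N, L)
        blocks.append(w.reshape(w.shape[0], n_elec * n_lags))
        frames.append(np.arange(a, b - n_lags + 1))
    return np.ascontiguousarray(np.vstack(blocks)), np.concatenate(frames)


# ---------------------------------------------------------------------------
# Coordinate descent
# ---------------------------------------------------------------------------


def coordinate_descent(
    X_train: np.ndarray,
    Y_train: np.ndarray,
    X_val: np.ndarray | None,
    Y_val: np.ndarray | None,
    config: FitConfig,
):
    """Greedy forward-stagewise coordinate descent for multiple targets.

    Each target column is fitted independently (the mathematics is
    per-channel; the loop is shared for efficiency): at every iteration the
    coordinate with the largest normalized gradient is nudged by a fixed
    small step, and the iterate with the best validation MSE is retained.
    Early stopping triggers after ``patience`` consecutive non-improving
    iterations. Returns ``(weights [P, C], n_iterations, best_val_mse)``.
    """
    Y_train = np.atleast_2d(Y_train.T).T if Y_train.ndim == 1 else Y_train
    T, P = X_train.shape
    C = Y_train.shape[1]
    if not (np.all(np.isfinite(X_train)) and np.all(np.isfinite(Y_train))):
        raise InvalidInputError("non-finite values in fitting data")

    use_val = config.patience is not None and X_val is not None and X_val.size
    norms = np.sqrt((X_train**2).sum(axis=0))
    norms_safe = np.where(norms > 0, norms, np.inf)
    sdx = X_train.std(axis=0)
    sdx = np.where(sdx > 0, sdx, np.inf)
    sdy = Y_train.std(axis=0)
    sdy = np.where(sdy > 0, sdy, 1.0)

    W = np.zeros((P, C))
    best_W = np.zeros((P, C))
    resid = Y_train.copy()
    if use_val:
        val_pred = np.zeros_like(Y_val, dtype=float)
        best_mse = ((Y_val - val_pred) ** 2).mean(axis=0)
        stall = np.zeros(C, dtype=int)
    active = np.ones(C, dtype=bool)
    n_iter = 0

    for it in range(config.max_iter):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        n_iter = it + 1
        G = X_train.T @ resid[:, idx]  # (P, n_active)
        j = np.argmax(np.abs(G) / norms_safe[:, None], axis=0)
        g = G[j, np.arange(idx.size)]
        delta = config.step_scale * (sdy[idx] / sdx[j]) * np.sign(g)
        cols = X_train[:, j]  # (T, n_active)
        resid[:, idx] -= cols * delta
        W[j, idx] += delta
        if use_val:
            val_pred[:, idx] += X_val[:, j] * delta
            mse = ((Y_val[:, idx] - val_pred[:, idx]) ** 2).mean(axis=0)
            improved = mse < best_mse[idx]
            imp_idx = idx[improved]
            best_mse[imp_idx] = mse[improved]
            best_W[:, imp_idx] = W[:, imp_idx]
            stall[imp_idx] = 0
            stall[idx[~improved]] += 1
            active[idx[stall[idx] > config.patience]] = False
        # without validation, run to max_iter and keep the final iterate

    if use_val:
        return best_W, n_iter, best_mse
    final_mse = (resid**2).mean(axis=0)
    return W, n_iter, final_mse


# ---------------------------------------------------------------------------
# Fitting / prediction
# ---------------------------------------------------------------------------


def fit_reconstruction(
    stim,
    resp: NeuralResponseMatrix,
    split: tuple,
    config: FitConfig | None = None,
    stim_space: str = "spectrogram32",
) -> ReconstructionModel:
    """Fit decoding filters for every stimulus channel on one train/val split.

    ``split`` is a pair of trial-index arrays ``(train_trials, val_trials)``
    into the response's trial table.
    """
    config = config or FitConfig()
    S = as_feature_matrix(stim)
    if S.shape[1] != resp.n_frames:
        raise InvalidInputError("stimulus and response frame counts differ")
    train_trials, val_trials = split
    L = config.n_lags

    Xtr, ftr = _lagged_design(resp.values, _segments(resp, train_trials), L)
    Ytr = S[:, ftr].T
    if val_trials is not None and len(val_trials):
        Xva, fva = _lagged_design(resp.values, _segments(resp, val_trials), L)
        Yva = S[:, fva].T
    else:
        Xva = Yva = None
    W, n_iter, _ = coordinate_descent(Xtr, Ytr, Xva, Yva, config)
    log.debug("reconstruction fit stopped after %d iterations", n_iter)
    n_elec = resp.n_electrodes
    weights = W.T.reshape(S.shape[0], n_elec, L).transpose(0, 2, 1)
    return ReconstructionModel(weights, stim_space=stim_space)


def predict_stimulus(
    model: ReconstructionModel, resp: NeuralResponseMatrix, trial_subset=None
):
    """Apply the decoding filters to a response matrix.

    Returns a ``[n_channels, n_frames]`` array aligned with the response;
    edge frames at the end of each trial (where the forward lag window runs
    off the trial) are NaN-flagged.
    """
    if resp.n_electrodes != model.n_electrodes:
        raise InvalidInputError(
            f"model expects {model.n_electrodes} electrodes, "
            f"got {resp.n_electrodes}"
        )
    L = model.n_lags
    X, frames = _lagged_design(resp.values, _segments(resp, trial_subset), L)
    W = model.weights.transpose(0, 2, 1).reshape(model.n_channels, -1)  # (C, N*L)
    pred = np.full((model.n_channels, resp.n_frames), np.nan)
    pred[:, frames] = W @ X.T
    return pred


def evaluate_accuracy(recon, orig) -> AccuracyReport:
    """Per-channel Pearson r between reconstruction and original.

    NaN frames (edge flags) are excluded pairwise; zero-variance channels
    are excluded from the Fisher-z mean and counted.
    """
    A = as_feature_matrix(recon) if not isinstance(recon, np.ndarray) else recon
    B = as_feature_matrix(orig) if not isinstance(orig, np.ndarray) else orig
    if A.shape != B.shape:
        raise InvalidInputError("reconstruction and original shapes differ")
    C = A.shape[0]
    rs = np.full(C, np.nan)
    n_frames = 0
    for c in range(C):
        ok = np.isfinite(A[c]) & np.isfinite(B[c])
        n_frames = max(n_frames, int(ok.sum()))
        if ok.sum() < 3:
            continue
        a, b = A[c, ok], B[c, ok]
        if a.std() == 0 or b.std() == 0:
            continue
        rs[c] = np.corrcoef(a, b)[0, 1]
    n_excl = int(np.sum(~np.isfinite(rs)))
    if n_excl:
        log.info("excluded %d degenerate channels from accuracy mean", n_excl)
    mean_r = rstats.fisher_mean(rs) if np.any(np.isfinite(rs)) else np.nan
    return AccuracyReport(rs, mean_r, n_frames, n_excluded_channels=n_excl)


# ---------------------------------------------------------------------------
# Monte Carlo cross-validation
# ---------------------------------------------------------------------------


def run_monte_carlo_cv(
    stim,
    resp: NeuralResponseMatrix,
    plan: CvPlan,
    config: FitConfig | None = None,
    stim_space: str = "spectrogram32",
    min_trials: int = 10,
):
    """Repeated random-subsampling cross-validation over whole trials.

    Per resample: fit on train/validation trials, reconstruct the held-out
    test trials, and score per-channel accuracy. Weights are averaged over
    resamples and per-weight resampled statistics (mean, SE = SD over
    resamples, t-ratio) are attached. Partitions depend only on the plan, so
    two models compared under the same plan see byte-identical splits.
    """
    config = config or FitConfig()
    S = as_feature_matrix(stim)
    segs = resp.trial_segments()
    n_trials = len(segs)
    if n_trials < min_trials:
        raise InvalidInputError(f"need >= {min_trials} trials, got {n_trials}")
    parts = plan.partitions(n_trials)

    weight_stack = []
    per_channel = []
    n_test_frames = 0
    for train_idx, val_idx, test_idx in parts:
        model = fit_reconstruction(S, resp, (train_idx, val_idx), config, stim_space)
        pred = predict_stimulus(model, resp, trial_subset=test_idx)
        test_frames = np.concatenate(
            [np.arange(a, b) for a, b in _segments(resp, test_idx)]
        )
        report = evaluate_accuracy(pred[:, test_frames], S[:, test_frames])
        per_channel.append(report.per_channel_r)
        n_test_frames += report.n_test_frames
        weight_stack.append(model.weights.ravel())

    weight_stack = np.asarray(weight_stack)
    stats_flat = rstats.resample_stats(weight_stack)
    mean_weights = stats_flat.mean.reshape(S.shape[0], config.n_lags,
                                           resp.n_electrodes)
    model = ReconstructionModel(mean_weights, stim_space=stim_space,
                                resample_stats=stats_flat)

    per_channel = np.asarray(per_channel)  # (n_resamples, C)
    chan_mean = np.array(
        [
            rstats.fisher_mean(col[np.isfinite(col)])
            if np.any(np.isfinite(col))
            else np.nan
            for col in per_channel.T
        ]
    )
    finite = chan_mean[np.isfinite(chan_mean)]
    mean_r = rstats.fisher_mean(finite) if finite.size else np.nan
    report = AccuracyReport(
        chan_mean,
        mean_r,
        n_test_frames,
        n_excluded_channels=int(np.sum(~np.isfinite(chan_mean))),
    )
    return model, report


# ---------------------------------------------------------------------------
# Rate-resolved accuracy
# ---------------------------------------------------------------------------


def _rate_scale_of(spec_values: np.ndarray, template: AuditorySpectrogram):
    s = AuditorySpectrogram(
        np.clip(spec_values, 0, None), template.freq_centers_hz,
        template.frame_rate_hz
    )
    return compute_modulation_representation(s, reduced_form="rate_scale")


def rate_accuracy_from_rate_scale(recon60: np.ndarray, orig60, rates_hz) -> np.ndarray:
    """Average per-channel accuracy in the 60-channel rate-scale space down
    to 6 unsigned rates: Fisher-average over the scale axis and over the
    +/- rate signs."""
    rates_hz = np.asarray(rates_hz, float)
    report = evaluate_accuracy(recon60, orig60)
    n_scale = 5
    n_rate = rates_hz.size
    rs = report.per_channel_r.reshape(n_scale, n_rate)
    unsigned = np.unique(np.abs(rates_hz))
    out = np.empty(unsigned.size)
    for i, r in enumerate(unsigned):
        sel = rs[:, np.abs(rates_hz) == r].ravel()
        sel = sel[np.isfinite(sel)]
        out[i] = rstats.fisher_mean(sel) if sel.size else np.nan
    return out


def rate_resolved_accuracy(
    recon_spec: AuditorySpectrogram | np.ndarray,
    orig_spec: AuditorySpectrogram,
) -> np.ndarray:
    """Accuracy per temporal modulation rate (6 unsigned values).

    Both the reconstructed and original spectrograms are projected into the
    rate-scale modulation space through the same filterbank; per-channel
    correlations over the 60 components are averaged over scale and the two
    sweep directions.
    """
    recon_vals = (
        recon_spec.values
        if isinstance(recon_spec, AuditorySpectrogram)
        else np.asarray(recon_spec, float)
    )
    if recon_vals.shape[0] != orig_spec.n_freq:
        raise InvalidConfigError("reconstruction and original frequency axes differ")
    ok = np.all(np.isfinite(recon_vals), axis=0)
    m_recon = _rate_scale_of(recon_vals[:, ok], orig_spec)
    m_orig = _rate_scale_of(orig_spec.values[:, ok], orig_spec)
    return rate_accuracy_from_rate_scale(
        m_recon.flatten_channels(), m_orig.flatten_channels(), m_orig.rates_hz
    )


# ---------------------------------------------------------------------------
# Electrode-level summaries
# ---------------------------------------------------------------------------


def informative_electrodes(
    model: ReconstructionModel,
    alpha: float = 0.05,
    t_threshold: float = 2.5,
):
    """Electrodes carrying statistically reliable decoding weight.

    Per-weight t-ratios (df = n_resamples - 1) are converted to two-sided
    p-values and screened by Benjamini-Hochberg FDR at ``alpha``; an
    electrode is flagged when any of its weights passes both |t| >
    ``t_threshold`` and the FDR selection. Returns ``(electrode_indices,
    mean_abs_weight_per_electrode)``.
    """
    if model.resample_stats is None:
        raise InvalidInputError("model lacks resampled statistics")
    n_res = model.resample_stats.n_resamples
    if n_res < 3:
        raise InvalidInputError("informative-electrode screen needs >= 3 resamples")
    t = model.resample_stats.t_ratio.reshape(model.weights.shape)
    df = n_res - 1
    finite = np.isfinite(t)
    p = np.ones_like(t)
    p[finite] = 2.0 * sps.t.sf(np.abs(t[finite]), df)
    selected = np.zeros_like(t, dtype=bool)
    selected[finite] = rstats.fdr_select(p[finite], alpha)
    flags = selected & finite & (np.abs(np.where(finite, t, 0.0)) > t_threshold)
    per_elec = flags.any(axis=(0, 1))
    magnitude = np.abs(model.weights).mean(axis=(0, 1))
    return np.flatnonzero(per_elec), magnitude


def electrode_count_curve(
    stim,
    resp: NeuralResponseMatrix,
    plan: CvPlan,
    subset_sizes,
    n_draws: int = 3,
    seed: int = 0,
    config: FitConfig | None = None,
    min_trials: int = 10,
) -> np.ndarray:
    """Mean reconstruction accuracy as a function of electrode count.

    For each subset size, random electrode subsets are drawn and the full
    Monte Carlo CV accuracy is averaged over draws. The full-population size
    reuses all electrodes in a single draw.
    """
    rng = np.random.default_rng(seed)
    n_elec = resp.n_electrodes
    out = np.empty(len(subset_sizes))
    for i, size in enumerate(subset_sizes):
        if size > n_elec:
            raise InvalidConfigError(f"subset size {size} exceeds {n_elec} electrodes")
        draws = 1 if size == n_elec else n_draws
        accs = []
        for _ in range(draws):
            chans = (
                np.arange(n_elec)
                if size == n_elec
                else np.sort(rng.choice(n_elec, size=size, replace=False))
            )
            sub = NeuralResponseMatrix(
                resp.values[:, chans],
                resp.frame_rate_hz,
                band_hz=resp.band_hz,
                standardized=resp.standardized,
                trial_index=resp.trial_index,
            )
            _, report = run_monte_carlo_cv(
                stim, sub, plan, config, min_trials=min_trials
            )
            # a degenerate (all-zero) model has no defined correlation;
            # it contributes zero accuracy to the curve
            accs.append(report.mean_r if np.isfinite(report.mean_r) else 0.0)
        out[i] = rstats.fisher_mean(accs)
    return out
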