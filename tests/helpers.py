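"""Independent oracles and shared analysis drivers for the test suite."""

import numpy as np

from speechdecode.audio_frontend import (
    AuditorySpectrogram,
    compute_modulation_representation,
)
from speechdecode.decoder import (
    FitConfig,
    fit_reconstruction,
    predict_stimulus,
    rate_accuracy_from_rate_scale,
)
from speechdecode import stats as rstats


def exhaustive_dtw_cost(cost: np.ndarray) -> float:
    """Minimum alignment cost by brute-force path enumeration.

    Recursively explores every monotone path using the same step pattern as
    the production dynamic program (diagonal, down, right), independent of
    it. Only feasible for small matrices.
    """
    m, n = cost.shape

    def rec(i, j):
        c = cost[i, j]
        if i == m - 1 and j == n - 1:
            return c
        best = np.inf
        if i + 1 < m and j + 1 < n:
            best = min(best, rec(i + 1, j + 1))
        if i + 1 < m:
            best = min(best, rec(i + 1, j))
        if j + 1 < n:
            best = min(best, rec(i, j + 1))
        return c + best

    return rec(0, 0)


def bh_select_oracle(p, alpha):
    """Hand-rolled Benjamini-Hochberg step-up, independent of statsmodels."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p)
    thresh = alpha * (np.arange(1, m + 1)) / m
    passed = np.flatnonzero(p[order] <= thresh)
    out = np.zeros(m, dtype=bool)
    if passed.size:
        out[order[: passed[-1] + 1]] = True
    return out


def random_gabor_strf(seed, n_freq=32, n_lags=100, frame_rate=100.0,
                      fmin=180.0, fmax=7000.0):
    """Random smooth STRF: a few spectro-temporal Gabor components."""
    rng = np.random.default_rng(seed)
    dx = np.log2(fmax / fmin) / (n_freq - 1)
    t = np.arange(n_lags) / frame_rate
    x = np.arange(n_freq) * dx
    w = np.zeros((n_freq, n_lags))
    for _ in range(rng.integers(2, 5)):
        r0 = np.exp(rng.uniform(np.log(1.0), np.log(32.0)))
        c0 = np.exp(rng.uniform(np.log(0.5), np.log(4.0)))
        t0 = rng.uniform(0.05, 0.4)
        x0 = rng.uniform(x[0], x[-1])
        gt = np.exp(-0.5 * ((t - t0) * r0 * 2) ** 2) * np.cos(
            2 * np.pi * r0 * (t - t0) + rng.uniform(0, 2 * np.pi)
        )
        gx = np.exp(-0.5 * ((x - x0) * c0 * 2) ** 2) * np.cos(
            2 * np.pi * c0 * (x - x0) + rng.uniform(0, 2 * np.pi)
        )
        w += rng.uniform(0.5, 1.0) * np.outer(gx, gt)
    return w


SIGNED_RATES = np.concatenate(
    [-np.array([32.0, 16.0, 8.0, 4.0, 2.0, 1.0]), np.array([1.0, 2.0, 4.0, 8.0, 16.0, 32.0])]
)


def cv_rate_accuracy(ds, plan, config, space):
    """Rate-resolved CV decoding accuracy for one stimulus space.

    Fits the reconstruction per resample, reconstructs held-out trials, and
    Fisher-averages per-trial rate-band accuracies. Spectrogram-space
    reconstructions are projected through the modulation filterbank before
    comparison; rate-scale reconstructions are compared channel-wise.
    """
    resp = ds.responses
    segs = resp.trial_segments()
    stim = ds.stim_features[
        "spectrogram32" if space == "spectrogram32" else "rate_scale60"
    ]
    rows = []
    for train_idx, val_idx, test_idx in plan.partitions(len(segs)):
        model = fit_reconstruction(stim, resp, (train_idx, val_idx), config, space)
        pred = predict_stimulus(model, resp, trial_subset=test_idx)
        for ti in test_idx:
            a, b = segs[ti]
            recon, orig = pred[:, a:b], stim[:, a:b]
            ok = np.all(np.isfinite(recon), axis=0)
            if space == "spectrogram32":
                sp = AuditorySpectrogram(
                    np.clip(recon[:, ok], 0, None), ds.freq_centers_hz
                )
                so = AuditorySpectrogram(orig[:, ok], ds.freq_centers_hz)
                mr = compute_modulation_representation(sp, reduced_form="rate_scale")
                mo = compute_modulation_representation(so, reduced_form="rate_scale")
                rows.append(
                    rate_accuracy_from_rate_scale(
                        mr.flatten_channels(), mo.flatten_channels(), mr.rates_hz
                    )
                )
            else:
                rows.append(
                    rate_accuracy_from_rate_scale(
                        recon[:, ok], orig[:, ok], SIGNED_RATES
                    )
                )
    rows = np.asarray(rows)
    return np.array(
        [
            rstats.fisher_mean(col[np.isfinite(col)])
            if np.any(np.isfinite(col))
            else np.nan
            for col in rows.T
        ]
    )


def decode_word_reconstructions(ds, n_folds=4, seed=0,
                                config=None):
    """Round-robin decoding so every word gets a held-out reconstruction."""
    config = config or FitConfig(step_scale=5e-3, max_iter=2500)
    resp = ds.responses
    segs = resp.trial_segments()
    S32 = ds.stim_features["spectrogram32"]
    n = len(segs)
    rng = np.random.default_rng(seed)
    folds = np.array_split(rng.permutation(n), n_folds)
    recons = [None] * n
    for test_idx in folds:
        rest = np.setdiff1d(np.arange(n), test_idx)
        val, train = rest[:5], rest[5:]
        model = fit_reconstruction(S32, resp, (train, val), config)
        pred = predict_stimulus(model, resp, trial_subset=test_idx)
        for ti in test_idx:
            a, _ = segs[ti]
            wf = int(ds.trial_table["word_frames"].iloc[ti])
            rec = np.clip(np.nan_to_num(pred[:, a:a + wf]), 0, None)
            recons[ti] = AuditorySpectrogram(rec, ds.freq_centers_hz)
    return recons
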