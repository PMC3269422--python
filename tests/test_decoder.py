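import numpy as np
import pytest

from speechdecode import stats as rstats
from speechdecode.decoder import (
    CvPlan,
    FitConfig,
    ReconstructionModel,
    coordinate_descent,
    electrode_count_curve,
    evaluate_accuracy,
    fit_reconstruction,
    informative_electrodes,
    predict_stimulus,
    rate_resolved_accuracy,
    run_monte_carlo_cv,
)
from speechdecode.decoder import _lagged_design
from speechdecode.exceptions import InvalidConfigError, InvalidInputError
from speechdecode.neural_preproc import NeuralResponseMatrix


def _noiseless_problem(seed=0, T=600, N=3, L=20, C=2, n_trials=6):
    """Responses random; stimulus generated from known decoding filters."""
    rng = np.random.default_rng(seed)
    resp_vals = rng.standard_normal((T, N))
    trial_index = np.repeat(np.arange(n_trials), T // n_trials)
    resp = NeuralResponseMatrix(resp_vals, trial_index=trial_index,
                                standardized=True)
    g = np.zeros((C, L, N))
    g[0, 3, 0], g[0, 7, 2] = 1.0, -0.5
    g[1, 0, 1], g[1, 15, 0] = 0.8, 0.3
    X, frames = _lagged_design(resp_vals, resp.trial_segments(), L)
    S = np.zeros((C, T))
    S[:, frames] = g.transpose(0, 2, 1).reshape(C, -1) @ X.T
    return S, resp, g


class TestFitReconstruction:
    def test_noiseless_recovery(self):
        """Known filters are recovered and held-out prediction is exact."""
        S, resp, g = _noiseless_problem()
        cfg = FitConfig(step_scale=5e-3, max_iter=20000, n_lags=20)
        model = fit_reconstruction(S, resp, (np.arange(4), [4]), cfg)
        assert np.corrcoef(model.weights.ravel(), g.ravel())[0, 1] > 0.95
        pred = predict_stimulus(model, resp, trial_subset=[5])
        a, b = resp.trial_segments()[5]
        rep = evaluate_accuracy(pred[:, a:b], S[:, a:b])
        assert rep.mean_r > 0.95

    def test_pure_noise_gives_near_zero_model(self):
        rng = np.random.default_rng(1)
        S, resp, _ = _noiseless_problem(seed=2)
        noise_stim = rng.standard_normal(S.shape)
        cfg = FitConfig(step_scale=1e-3, max_iter=3000, n_lags=20)
        model = fit_reconstruction(noise_stim, resp, (np.arange(4), [4]), cfg)
        assert np.abs(model.weights).max() < 0.2
        pred = predict_stimulus(model, resp, trial_subset=[5])
        a, b = resp.trial_segments()[5]
        rep = evaluate_accuracy(pred[:, a:b], noise_stim[:, a:b])
        assert not (rep.mean_r > 0.3)

    def test_default_filter_dimensionality(self):
        """Each stimulus channel gets n_electrodes x 100 lag parameters."""
        rng = np.random.default_rng(3)
        resp = NeuralResponseMatrix(
            rng.standard_normal((600, 4)),
            trial_index=np.repeat(np.arange(4), 150),
        )
        S = rng.standard_normal((2, 600))
        model = fit_reconstruction(S, resp, (np.arange(3), [3]),
                                   FitConfig(max_iter=10))
        assert model.weights.shape == (2, 100, 4)
        assert model.n_lags == 100

    def test_nan_rejected(self):
        S, resp, _ = _noiseless_problem()
        S[0, 0] = np.nan
        with pytest.raises(InvalidInputError):
            fit_reconstruction(S, resp, (np.arange(4), [4]),
                               FitConfig(max_iter=10, n_lags=20))

    def test_sparsity_of_short_fits(self):
        S, resp, _ = _noiseless_problem()
        cfg = FitConfig(step_scale=1e-3, max_iter=200, n_lags=20)
        model = fit_reconstruction(S, resp, (np.arange(4), [4]), cfg)
        assert np.mean(model.weights == 0.0) > 0.5


class TestPredictStimulus:
    def test_zero_response_zero_prediction(self):
        model = ReconstructionModel(np.random.default_rng(0).standard_normal(
            (2, 10, 3)))
        resp = NeuralResponseMatrix(np.zeros((50, 3)))
        pred = predict_stimulus(model, resp)
        assert np.nanmax(np.abs(pred)) == 0.0

    def test_delta_filter_shifts_response(self):
        """g(tau0, f0, n0) = 1 makes the prediction a lagged copy of R."""
        rng = np.random.default_rng(1)
        vals = rng.standard_normal((60, 2))
        resp = NeuralResponseMatrix(vals)
        w = np.zeros((1, 10, 2))
        w[0, 4, 1] = 1.0
        pred = predict_stimulus(ReconstructionModel(w), resp)
        valid = np.isfinite(pred[0])
        np.testing.assert_allclose(pred[0, valid],
                                   vals[4:4 + valid.sum(), 1])

    def test_electrode_mismatch_rejected(self):
        model = ReconstructionModel(np.zeros((1, 10, 3)))
        with pytest.raises(InvalidInputError):
            predict_stimulus(model, NeuralResponseMatrix(np.zeros((50, 2))))


class TestEvaluateAccuracy:
    def test_identity_gives_unit_correlation(self):
        x = np.random.default_rng(0).standard_normal((4, 100))
        rep = evaluate_accuracy(x, x.copy())
        np.testing.assert_allclose(rep.per_channel_r, 1.0)
        assert rep.mean_r == pytest.approx(1.0, abs=1e-6)

    def test_fisher_mean_of_equal_values(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal((2, 2000))
        # construct channels with identical target correlation ~0.5
        b = 0.5 * (a / a.std(axis=1, keepdims=True)) \
            + np.sqrt(1 - 0.25) * rng.standard_normal(a.shape)
        rep = evaluate_accuracy(b, a)
        expected = rstats.fisher_mean(rep.per_channel_r)
        assert rep.mean_r == pytest.approx(expected)

    def test_hand_computed_fisher_mean(self):
        # channels engineered to r = 0.8 and 0.2 within numerical tolerance
        rs = np.array([0.8, 0.2])
        expected = np.tanh(np.mean(np.arctanh(rs)))
        assert rstats.fisher_mean(rs) == pytest.approx(expected)

    def test_zero_variance_channel_excluded(self):
        rng = np.random.default_rng(2)
        a = rng.standard_normal((2, 50))
        b = a.copy()
        b[1] = 0.0
        rep = evaluate_accuracy(b, a)
        assert rep.n_excluded_channels == 1
        assert np.isnan(rep.per_channel_r[1])
        assert rep.mean_r == pytest.approx(1.0, abs=1e-6)


class TestMonteCarloCv:
    def _dataset(self, seed=0, signal=True):
        rng = np.random.default_rng(seed)
        T, N, n_trials = 1500, 3, 15
        resp_vals = rng.standard_normal((T, N))
        trial_index = np.repeat(np.arange(n_trials), T // n_trials)
        resp = NeuralResponseMatrix(resp_vals, trial_index=trial_index,
                                    standardized=True)
        g = rng.standard_normal((2, 20, N)) * (rng.random((2, 20, N)) < 0.1)
        X, frames = _lagged_design(resp_vals, resp.trial_segments(), 20)
        S = np.zeros((2, T))
        S[:, frames] = g.transpose(0, 2, 1).reshape(2, -1) @ X.T
        S += 0.3 * S.std() * rng.standard_normal(S.shape)
        if not signal:
            S = rng.standard_normal(S.shape)
        return S, resp

    def test_identical_partitions_for_identical_plans(self):
        plan_a = CvPlan(n_resamples=4, seed=11)
        plan_b = CvPlan(n_resamples=4, seed=11)
        for (tr_a, va_a, te_a), (tr_b, va_b, te_b) in zip(
            plan_a.partitions(15), plan_b.partitions(15)
        ):
            np.testing.assert_array_equal(tr_a, tr_b)
            np.testing.assert_array_equal(va_a, va_b)
            np.testing.assert_array_equal(te_a, te_b)

    def test_cv_recovers_signal_and_reports_stats(self):
        S, resp = self._dataset()
        cfg = FitConfig(step_scale=5e-3, max_iter=1500, n_lags=20)
        model, report = run_monte_carlo_cv(S, resp, CvPlan(3, seed=1), cfg)
        assert report.mean_r > 0.5
        assert model.resample_stats.n_resamples == 3
        assert model.weights.shape == (2, 20, 3)

    def test_resample_count_stability(self):
        """Mean accuracy is stable in the number of resamples."""
        S, resp = self._dataset(seed=4)
        cfg = FitConfig(step_scale=5e-3, max_iter=800, n_lags=20)
        _, r3 = run_monte_carlo_cv(S, resp, CvPlan(3, seed=2), cfg)
        _, r6 = run_monte_carlo_cv(S, resp, CvPlan(6, seed=2), cfg)
        assert abs(r3.mean_r - r6.mean_r) < 0.15

    def test_shuffled_label_control_near_zero(self):
        S, resp = self._dataset(seed=5, signal=False)
        cfg = FitConfig(step_scale=2e-3, max_iter=600, n_lags=20)
        _, report = run_monte_carlo_cv(S, resp, CvPlan(3, seed=3), cfg)
        assert abs(report.mean_r) < 0.25

    def test_too_few_trials_rejected(self):
        S, resp = self._dataset()
        with pytest.raises(InvalidInputError):
            run_monte_carlo_cv(S, resp, CvPlan(2, seed=0), min_trials=99)


class TestInformativeElectrodes:
    def _model_with_stats(self, t_values, n_resamples=10):
        """Model whose per-weight t-ratios are prescribed."""
        C, L, N = 1, 2, len(t_values)
        weights = np.ones((C, L, N))
        se = np.ones(C * L * N)
        mean = np.zeros(C * L * N)
        t = np.zeros((C, L, N))
        for n, tv in enumerate(t_values):
            t[0, 0, n] = tv
        flat_t = t.ravel()
        mean = flat_t * se
        stats = rstats.ResampleEstimate(mean=mean, se=se, t_ratio=flat_t,
                                        n_resamples=n_resamples)
        return ReconstructionModel(weights, resample_stats=stats)

    def test_threshold_boundary_excluded(self):
        model = self._model_with_stats([2.4, 0.0, 0.0])
        flagged, _ = informative_electrodes(model)
        assert 0 not in flagged

    def test_strong_electrode_flagged(self):
        model = self._model_with_stats([8.0, 0.1, 0.2])
        flagged, mags = informative_electrodes(model)
        assert list(flagged) == [0]
        assert mags.shape == (3,)

    def test_all_zero_weights_give_empty_set(self):
        model = self._model_with_stats([0.0, 0.0])
        flagged, _ = informative_electrodes(model)
        assert len(flagged) == 0

    def test_planted_electrode_recovered_from_cv(self):
        """CV resampling flags the signal-carrying electrode only."""
        rng = np.random.default_rng(6)
        T, n_trials = 1500, 15
        strong = rng.standard_normal(T)
        resp_vals = np.column_stack([strong, rng.standard_normal((T, 2))])
        resp = NeuralResponseMatrix(
            resp_vals, trial_index=np.repeat(np.arange(n_trials), T // n_trials),
            standardized=True,
        )
        S = (strong + 0.2 * rng.standard_normal(T))[None, :]
        cfg = FitConfig(step_scale=5e-3, max_iter=800, n_lags=10)
        model, _ = run_monte_carlo_cv(S, resp, CvPlan(5, seed=4), cfg)
        flagged, _ = informative_electrodes(model)
        assert 0 in flagged and 1 not in flagged and 2 not in flagged

    def test_too_few_resamples_refused(self):
        model = self._model_with_stats([5.0], n_resamples=2)
        with pytest.raises(InvalidInputError):
            informative_electrodes(model)


class TestRateResolvedAccuracy:
    def test_identity_gives_unit_accuracy(self, word_spectrogram_32):
        rr = rate_resolved_accuracy(word_spectrogram_32, word_spectrogram_32)
        assert rr.shape == (6,)
        np.testing.assert_allclose(rr, 1.0, atol=1e-9)

    def test_lowpass_degradation_hits_fast_rates(self, word_spectrogram_32):
        from scipy import signal as sg

        b, a = sg.butter(3, 4.0 / 50.0)
        blurred = sg.filtfilt(b, a, word_spectrogram_32.values, axis=1)
        rr = rate_resolved_accuracy(np.clip(blurred, 0, None),
                                    word_spectrogram_32)
        slow = rstats.fisher_mean(rr[:2])
        fast = rstats.fisher_mean(rr[4:])
        assert slow > fast

    def test_mismatched_axes_rejected(self, word_spectrogram_32):
        with pytest.raises(InvalidConfigError):
            rate_resolved_accuracy(np.ones((16, 100)), word_spectrogram_32)


class TestElectrodeCountCurve:
    def test_accuracy_non_decreasing_and_degenerate_subset(self):
        rng = np.random.default_rng(8)
        T, N, n_trials = 1200, 8, 12
        resp_vals = rng.standard_normal((T, N))
        resp = NeuralResponseMatrix(
            resp_vals, trial_index=np.repeat(np.arange(n_trials), T // n_trials),
            standardized=True,
        )
        S = (resp_vals @ rng.standard_normal((N, 1))).T
        S = S + 0.5 * S.std() * rng.standard_normal(S.shape)
        cfg = FitConfig(step_scale=5e-3, max_iter=400, n_lags=10)
        plan = CvPlan(2, seed=5)
        curve = electrode_count_curve(S, resp, plan, [1, 4, 8], n_draws=2,
                                      seed=0, config=cfg)
        assert curve[0] <= curve[1] + 0.05 and curve[1] <= curve[2] + 0.05
        # full population equals the plain CV run under the same plan
        _, full = run_monte_carlo_cv(S, resp, plan, cfg)
        assert curve[2] == pytest.approx(full.mean_r, abs=1e-12)
        with pytest.raises(InvalidConfigError):
            electrode_count_curve(S, resp, plan, [9], config=cfg)


class TestAffineInvariance:
    def test_accuracy_invariant_to_electrode_rescaling(self):
        """Affine per-electrode changes vanish after standardization."""
        from speechdecode.neural_preproc import zscore_columns

        rng = np.random.default_rng(9)
        T, N, n_trials = 1000, 3, 10
        raw = rng.standard_normal((T, N))
        g = rng.standard_normal((1, 10, N))
        trial_index = np.repeat(np.arange(n_trials), T // n_trials)

        def run(vals):
            resp = NeuralResponseMatrix(zscore_columns(vals),
                                        trial_index=trial_index,
                                        standardized=True)
            X, frames = _lagged_design(resp.values, resp.trial_segments(), 10)
            S = np.zeros((1, T))
            S[:, frames] = g.transpose(0, 2, 1).reshape(1, -1) @ X.T
            cfg = FitConfig(step_scale=5e-3, max_iter=500, n_lags=10)
            _, rep = run_monte_carlo_cv(S, resp, CvPlan(2, seed=6), cfg)
            return rep.mean_r

        scaled = raw * np.array([3.0, 0.5, 10.0]) + np.array([1.0, -2.0, 0.3])
        assert run(raw) == pytest.approx(run(scaled), abs=1e-8)
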