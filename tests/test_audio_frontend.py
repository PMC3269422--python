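import numpy as np
import pytest
from scipy import signal

from speechdecode import (
    AuditorySpectrogram,
    ModulationRepresentation,
    Waveform,
    compute_auditory_spectrogram,
    compute_modulation_representation,
    downsample_spectrogram,
    invert_modulation_to_spectrogram,
    invert_spectrogram_to_waveform,
)
from speechdecode.audio_frontend import _gammatone_bank
from speechdecode.exceptions import InvalidConfigError, InvalidInputError
from speechdecode.synthetic_data import generate_stimuli


class TestAuditorySpectrogram:
    def test_tone_peaks_at_matching_channel(self):
        """A 1 kHz tone peaks at the channel brute-force filtering selects."""
        fs = 16000
        t = np.arange(fs) / fs
        w = Waveform(np.sin(2 * np.pi * 1000.0 * t), fs)
        s = compute_auditory_spectrogram(w)
        assert s.values.shape == (128, 100)
        got = int(np.argmax(s.values.mean(axis=1)))

        # independent oracle: RMS of each filter output via direct lfilter
        centers, kernels = _gammatone_bank(fs, 128, 180.0, 7000.0)
        rms = [
            np.sqrt(np.mean(signal.lfilter(b, [1.0], w.samples) ** 2))
            for b in kernels
        ]
        assert got == int(np.argmax(rms))
        assert abs(got - int(np.argmin(np.abs(centers - 1000.0)))) <= 1

    def test_zero_waveform_gives_floor(self):
        s = compute_auditory_spectrogram(Waveform(np.zeros(16000), 16000))
        assert np.all(s.values == 0.0)

    def test_one_second_default_shape(self):
        w = Waveform(np.random.default_rng(0).standard_normal(16000), 16000)
        s = compute_auditory_spectrogram(w)
        assert s.values.shape == (128, 100)
        assert s.frame_rate_hz == 100.0

    def test_empty_and_bad_config_errors(self):
        with pytest.raises(InvalidInputError):
            compute_auditory_spectrogram(Waveform(np.array([]), 16000))
        with pytest.raises(InvalidConfigError):
            compute_auditory_spectrogram(
                Waveform(np.ones(16000), 16000), fmax=9000.0
            )


class TestDownsample:
    def test_group_means_and_axis(self):
        rng = np.random.default_rng(1)
        vals = np.abs(rng.standard_normal((128, 10)))
        s = AuditorySpectrogram(vals, np.geomspace(180, 7000, 128))
        d = downsample_spectrogram(s, 32)
        assert d.values.shape == (32, 10)
        # hand-computed group means for the first two groups
        np.testing.assert_allclose(d.values[0], vals[:4].mean(axis=0))
        np.testing.assert_allclose(d.values[1], vals[4:8].mean(axis=0))
        # output axis stays log-spaced
        dlog = np.diff(np.log(d.freq_centers_hz))
        np.testing.assert_allclose(dlog, dlog[0], rtol=1e-6)

    def test_constant_preserved(self):
        s = AuditorySpectrogram(np.full((128, 5), 3.7), np.geomspace(180, 7000, 128))
        d = downsample_spectrogram(s, 32)
        np.testing.assert_allclose(d.values, 3.7)

    def test_non_divisible_rejected(self):
        s = AuditorySpectrogram(np.ones((128, 5)), np.geomspace(180, 7000, 128))
        with pytest.raises(InvalidConfigError):
            downsample_spectrogram(s, 33)


class TestModulationRepresentation:
    def test_channel_counts(self, word_spectrogram_32):
        m = compute_modulation_representation(word_spectrogram_32, reduced_form="full")
        assert m.values.shape[:3] == (5, 12, 32)
        assert m.n_channels == 1920
        rs = compute_modulation_representation(
            word_spectrogram_32, reduced_form="rate_scale"
        )
        assert rs.n_channels == 60
        ro = compute_modulation_representation(
            word_spectrogram_32, reduced_form="rate_only"
        )
        assert ro.n_channels == 6

    def test_constant_input_has_no_modulation_energy(self, freq_axis_32):
        s = AuditorySpectrogram(np.ones((32, 100)), freq_axis_32)
        for form in ("full", "rate_scale", "rate_only"):
            m = compute_modulation_representation(s, reduced_form=form)
            assert m.values.max() < 1e-10

    def test_am_tone_rate_profile_peaks_at_4hz(self, am_tone_spectrogram):
        s32 = downsample_spectrogram(am_tone_spectrogram)
        ro = compute_modulation_representation(s32, reduced_form="rate_only")
        steady = ro.values[:, 60:]
        assert ro.rates_hz[int(np.argmax(steady.mean(axis=1)))] == 4.0

        # oracle: modulus of the 2-D FFT of the steady-state spectrogram,
        # marginalized over spectral frequency, ranks 4 Hz highest among
        # the analysis rates
        block = s32.values[:, 50:150]
        spec2d = np.abs(np.fft.fft2(block - block.mean()))
        ft = np.fft.fftfreq(block.shape[1], d=0.01)
        def band_energy(r):
            sel = (np.abs(ft) >= r / np.sqrt(2)) & (np.abs(ft) < r * np.sqrt(2))
            return spec2d[:, sel].mean()
        energies = {r: band_energy(r) for r in (1.0, 2.0, 4.0, 8.0, 16.0, 32.0)}
        assert max(energies, key=energies.get) == 4.0

    def test_constant_rate_magnitude_near_constant(self, am_tone_spectrogram):
        """Energy coding: a constant-rate AM tone yields a steady magnitude."""
        m = compute_modulation_representation(am_tone_spectrogram, reduced_form="full")
        steady = m.values[..., 60:160]
        idx = np.unravel_index(np.argmax(steady.mean(axis=-1)), steady.shape[:-1])
        x = steady[idx]
        assert x.std() / x.mean() < 0.1

    def test_modulation_phase_invariance(self):
        """Shifting the AM phase by 90 deg barely changes the magnitudes.

        Steady state starts only after the slowest (1 Hz) analysis kernel
        has fully entered the signal, so a long tone is analyzed and the
        4.5-5.5 s window compared.
        """
        specs = []
        for phase in (0.0, np.pi / 2):
            w = generate_stimuli(
                "am_tone",
                {"carrier_hz": 1000.0, "rate_hz": 4.0, "duration_s": 6.0,
                 "mod_phase": phase},
                1, 0,
            )[0]
            m = compute_modulation_representation(
                compute_auditory_spectrogram(w), reduced_form="full"
            )
            specs.append(m.values[..., 450:550].mean(axis=-1))
        a, b = specs
        assert np.abs(a - b).max() / a.max() < 0.05

    def test_energy_monotone_in_modulation_depth(self):
        totals = []
        for depth in (0.2, 0.5, 1.0):
            w = generate_stimuli(
                "am_tone", {"rate_hz": 4.0, "depth": depth, "duration_s": 1.5}, 1, 0
            )[0]
            s32 = downsample_spectrogram(compute_auditory_spectrogram(w))
            m = compute_modulation_representation(s32, reduced_form="rate_only")
            totals.append(m.values.sum())
        assert totals[0] < totals[1] < totals[2]

    def test_unknown_form_rejected(self, word_spectrogram_32):
        with pytest.raises(InvalidConfigError):
            compute_modulation_representation(
                word_spectrogram_32, reduced_form="bogus"
            )


class TestModulationInversion:
    def test_roundtrip_recovers_spectrogram(self, word_spectrogram_32):
        m = compute_modulation_representation(
            word_spectrogram_32, reduced_form="full"
        )
        rec = invert_modulation_to_spectrogram(m, n_init=3, seed=0, max_iter=50)
        r = np.corrcoef(rec.values.ravel(), word_spectrogram_32.values.ravel())[0, 1]
        assert r >= 0.70  # recovery is imperfect: magnitude-only, DC in null space

    def test_iterations_reduce_magnitude_mismatch(self, word_spectrogram_32):
        """The projection iterations converge in the algorithm's own
        objective: the modulation magnitudes of the iterate approach the
        targets. (Correlation with the source is not the iteration
        objective and need not improve monotonically in phase retrieval.)"""
        m = compute_modulation_representation(
            word_spectrogram_32, reduced_form="full"
        )
        resid = []
        for iters in (1, 10):
            rec = invert_modulation_to_spectrogram(
                m, n_init=1, seed=0, max_iter=iters, tol=0.0
            )
            m2 = compute_modulation_representation(rec, reduced_form="full")
            resid.append(np.linalg.norm(m2.values - m.values)
                         / np.linalg.norm(m.values))
        assert resid[1] < resid[0]

    def test_zero_magnitude_gives_floor(self, word_spectrogram_32):
        m = compute_modulation_representation(
            word_spectrogram_32, reduced_form="full"
        )
        zero = ModulationRepresentation(
            np.zeros_like(m.values), m.rates_hz, m.scales_cyc_per_oct,
            "full", m.frame_rate_hz, m.freq_centers_hz,
        )
        rec = invert_modulation_to_spectrogram(zero, n_init=2, seed=0, max_iter=5)
        assert np.all(rec.values == 0.0)

    def test_seeded_determinism(self, word_spectrogram_32):
        m = compute_modulation_representation(
            word_spectrogram_32, reduced_form="full"
        )
        a = invert_modulation_to_spectrogram(m, n_init=2, seed=4, max_iter=10)
        b = invert_modulation_to_spectrogram(m, n_init=2, seed=4, max_iter=10)
        np.testing.assert_array_equal(a.values, b.values)


class TestWaveformInversion:
    def test_tone_roundtrip_channel(self):
        fs = 16000
        t = np.arange(fs // 2) / fs
        w = Waveform(np.sin(2 * np.pi * 1000.0 * t), fs)
        s = downsample_spectrogram(compute_auditory_spectrogram(w))
        rec = invert_spectrogram_to_waveform(s, n_iter=10, seed=0)
        s2 = compute_auditory_spectrogram(rec, n_channels=32)
        orig_ch = int(np.argmax(s.values.mean(axis=1)))
        rec_ch = int(np.argmax(s2.values.mean(axis=1)))
        assert abs(orig_ch - rec_ch) <= 1

    def test_silence_gives_silence(self, freq_axis_32):
        s = AuditorySpectrogram(np.zeros((32, 50)), freq_axis_32)
        rec = invert_spectrogram_to_waveform(s, n_iter=5, seed=0)
        assert np.max(np.abs(rec.samples)) < 1e-12

    def test_seeded_determinism(self, word_spectrogram_32):
        a = invert_spectrogram_to_waveform(word_spectrogram_32, n_iter=3, seed=1)
        b = invert_spectrogram_to_waveform(word_spectrogram_32, n_iter=3, seed=1)
        np.testing.assert_array_equal(a.samples, b.samples)
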