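"""EMG conditioning and feature suite against closed-form oracles."""

import numpy as np
import pytest
from scipy import signal as sps

from ulbench.emg_metrics import (
    EMGRecording,
    Envelope,
    cocontraction_index,
    condition,
    extract_synergies,
    frequency_features,
    intermuscular_coherence,
    muscle_onset,
    teager_kaiser,
    time_features,
)

RATE = 2000.0


def band_noise(n, rng, rate=RATE, band=(20.0, 450.0)):
    sos = sps.butter(4, band, btype="band", fs=rate, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    return x / np.std(x)


class TestConditioning:
    def test_notch_removes_mains_tone(self, rng):
        t = np.arange(int(4 * RATE)) / RATE
        x = np.sin(2 * np.pi * 50.0 * t)
        rec = EMGRecording(x[None, :], RATE, ("biceps_brachii",))
        filtered, _ = condition(rec, notch_50hz=True)
        # compare the 50 Hz spectral line before and after
        f, p_in = sps.welch(x, fs=RATE, nperseg=4096)
        _, p_out = sps.welch(filtered.data[0], fs=RATE, nperseg=4096)
        i50 = np.argmin(np.abs(f - 50.0))
        assert p_out[i50] < 0.01 * p_in[i50]

    def test_constant_burst_envelope_tracks_amplitude(self, rng):
        n = int(4 * RATE)
        carrier = band_noise(n, rng)
        a = 0.8
        rec = EMGRecording((a * carrier)[None, :], RATE, ("biceps_brachii",))
        _, env = condition(rec)
        mid = env.data[0, n // 4: 3 * n // 4]
        # envelope of rectified unit-variance noise: mean |x| * a
        assert np.mean(mid) == pytest.approx(a * np.sqrt(2 / np.pi), rel=0.1)

    def test_white_noise_envelope_positive(self, rng):
        rec = EMGRecording(band_noise(4096, rng)[None, :], RATE,
                           ("biceps_brachii",))
        _, env = condition(rec)
        assert np.all(env.data >= 0)

    def test_low_rate_warns(self, rng):
        with pytest.warns(UserWarning, match="1000"):
            EMGRecording(np.zeros((1, 100)), 800.0, ("biceps_brachii",))

    def test_unknown_muscle_rejected(self):
        with pytest.raises(ValueError, match="unknown muscle"):
            EMGRecording(np.zeros((1, 10)), RATE, ("flexor_hallucis",))


class TestTimeFeatures:
    def test_constant_signal(self):
        f = time_features(np.full(100, 0.4))
        assert f["waveform_length"] == 0.0
        assert f["emg_zero_crossing"] == 0
        assert f["slope_sign_change"] == 0
        assert f["root_mean_square"] == pytest.approx(0.4)
        assert f["activation_level"] == pytest.approx(0.4)
        assert f["variance_of_emg"] == pytest.approx(0.0)

    def test_sine_rms_and_zero_crossings(self):
        k, n = 5, 500  # sampling such that steps clear the 10 uV deadband
        t = np.arange(n) / n
        x = 0.7 * np.sin(2 * np.pi * k * t)
        f = time_features(x)
        assert f["root_mean_square"] == pytest.approx(0.7 / np.sqrt(2),
                                                      rel=1e-2)
        assert f["emg_zero_crossing"] in (2 * k - 1, 2 * k)

    def test_tiny_alternating_sequence_oracle(self):
        # hand-computed: WL = |−2|+|2|+|−2| = 6; 3 sign changes
        f = time_features(np.array([1.0, -1.0, 1.0, -1.0]))
        assert f["waveform_length"] == 6.0
        assert f["emg_zero_crossing"] == 3

    def test_rms_squared_equals_variance_on_zero_mean(self, rng):
        x = rng.standard_normal(2048)
        x -= x.mean()
        f = time_features(x)
        assert f["root_mean_square"] ** 2 == pytest.approx(
            f["variance_of_emg"], rel=1e-9)

    def test_mavs_subsegments(self):
        x = np.concatenate([np.full(100, 1.0), np.full(100, 2.0),
                            np.full(100, 4.0)])
        f = time_features(x, n_subsegments=3)
        assert f["mean_absolute_value_slope"] == pytest.approx([1.0, 2.0])


class TestFrequencyFeatures:
    def test_pure_tone_centroid_and_median(self):
        f0 = 120.0
        t = np.arange(int(4 * RATE)) / RATE
        x = np.sin(2 * np.pi * f0 * t)
        f = frequency_features(x, RATE)
        bin_hz = RATE / 512
        assert abs(f["mean_frequency"] - f0) < bin_hz
        assert abs(f["median_frequency"] - f0) < bin_hz
        assert f["power_spectrum_ratio"] > 0.9

    def test_two_equal_tones_mean_frequency(self):
        f1, f2 = 80.0, 240.0
        t = np.arange(int(8 * RATE)) / RATE
        x = np.sin(2 * np.pi * f1 * t) + np.sin(2 * np.pi * f2 * t)
        f = frequency_features(x, RATE)
        # discrete-spectrum oracle: centroid of two equal-power lines
        assert f["mean_frequency"] == pytest.approx((f1 + f2) / 2, rel=0.02)

    def test_flat_band_frequency_ratio(self, rng):
        x = band_noise(int(30 * RATE), rng)
        f = frequency_features(x, RATE)
        # flat-spectrum integral oracle: (60-20)/(450-60)
        assert f["frequency_ratio"] == pytest.approx(40 / 390, rel=0.25)

    def test_median_frequency_splits_power_in_half(self, rng):
        x = band_noise(int(10 * RATE), rng)
        f = frequency_features(x, RATE)
        freqs = np.asarray(f["power_spectral_density"]["f_hz"])
        p = np.asarray(f["power_spectral_density"]["psd"])
        below = p[freqs <= f["median_frequency"]].sum()
        assert below == pytest.approx(p.sum() / 2, rel=0.02)

    def test_short_window_rejected(self):
        with pytest.raises(ValueError, match="256"):
            frequency_features(np.zeros(100), RATE)


class TestMuscleOnset:
    def _burst_signal(self, latency_s, rng, go_cue_s=0.5, rate=RATE):
        n = int(2 * rate)
        t = np.arange(n) / rate
        x = 0.01 * band_noise(n, rng, rate)
        burst = (t >= go_cue_s + latency_s) & (t < go_cue_s + latency_s + 0.4)
        x[burst] += 0.15 * band_noise(int(burst.sum()), rng, rate)
        return x

    def test_injected_latency_recovered(self, rng):
        x = self._burst_signal(0.120, rng)
        lat = muscle_onset(x, RATE, go_cue_s=0.5)
        assert lat == pytest.approx(0.120, abs=0.015)

    def test_flat_noise_no_onset(self, rng):
        x = 0.01 * band_noise(int(2 * RATE), rng)
        assert muscle_onset(x, RATE, go_cue_s=0.5) is None

    def test_pre_cue_burst_ignored(self, rng):
        n = int(2 * RATE)
        t = np.arange(n) / RATE
        x = 0.01 * band_noise(n, rng)
        pre = (t >= 0.25) & (t < 0.45)
        x[pre] += 0.15 * band_noise(int(pre.sum()), rng)
        assert muscle_onset(x, RATE, go_cue_s=1.0) is None

    def test_tkeo_definition(self):
        x = np.array([0.0, 1.0, 2.0, 1.0, 0.0])
        psi = teager_kaiser(x)
        np.testing.assert_allclose(psi[1:-1],
                                   x[1:-1]**2 - x[:-2] * x[2:])

    def test_insufficient_baseline_rejected(self, rng):
        with pytest.raises(ValueError, match="baseline"):
            muscle_onset(band_noise(1000, rng), RATE, go_cue_s=0.05)


class TestCocontraction:
    def test_identical_envelopes_100_percent(self):
        e = np.abs(np.sin(np.linspace(0, 3, 500)))
        assert cocontraction_index(e, e) == pytest.approx(100.0)

    def test_disjoint_supports_zero(self):
        e1 = np.concatenate([np.ones(100), np.zeros(100)])
        e2 = np.concatenate([np.zeros(100), np.ones(100)])
        assert cocontraction_index(e1, e2) == 0.0

    def test_half_amplitude_closed_form(self):
        e1 = np.abs(np.sin(np.linspace(0, 3, 500))) + 0.1
        # oracle: 2 * sum(e1/2) / (1.5 * sum(e1)) = 2/3
        assert cocontraction_index(e1, e1 / 2) == pytest.approx(100 * 2 / 3)

    def test_symmetric_and_bounded(self, rng):
        e1 = np.abs(rng.standard_normal(300))
        e2 = np.abs(rng.standard_normal(300))
        c12 = cocontraction_index(e1, e2)
        assert c12 == pytest.approx(cocontraction_index(e2, e1))
        assert 0.0 <= c12 <= 100.0

    def test_zero_envelopes_not_computable(self):
        assert cocontraction_index(np.zeros(10), np.zeros(10)) is None


class TestCoherence:
    def test_identical_signals_unit_coherence(self, rng):
        x = band_noise(int(10 * RATE), rng)
        out = intermuscular_coherence(x, x, RATE)
        np.testing.assert_allclose(out["coherence"], 1.0, atol=1e-6)

    def test_independent_noise_below_confidence_level(self):
        # Monte-Carlo with fixed seeds: band mean under the 95% level
        hits = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            x = band_noise(int(31 * RATE / 2), r, rate=RATE)
            y = band_noise(int(31 * RATE / 2), r, rate=RATE)
            out = intermuscular_coherence(x, y, RATE)
            hits += out["band_mean"] < out["confidence_level_95"]
        assert hits >= 9

    def test_shared_band_raises_coherence(self, rng):
        n = int(20 * RATE)
        shared = band_noise(n, rng)
        sos = sps.butter(4, (15, 35), btype="band", fs=RATE, output="sos")
        common = sps.sosfiltfilt(sos, shared)
        x = common + 0.2 * band_noise(n, rng)
        y = common + 0.2 * band_noise(n, rng)
        out = intermuscular_coherence(x, y, RATE, band_hz=(15.0, 30.0))
        outside = intermuscular_coherence(x, y, RATE, band_hz=(100.0, 200.0))
        assert out["band_mean"] > outside["band_mean"]
        assert np.all((out["coherence"] >= 0) & (out["coherence"] <= 1))

    def test_too_short_rejected(self, rng):
        with pytest.raises(ValueError, match="segments"):
            intermuscular_coherence(np.zeros(100), np.zeros(100), RATE)


class TestSynergies:
    @staticmethod
    def _rank2(n=400, noise=0.0, seed=0):
        r = np.random.default_rng(seed)
        w0 = np.array([[1.0, 0.0], [0.8, 0.1], [0.0, 1.0], [0.1, 0.9],
                       [0.5, 0.5]])
        t = np.linspace(0, 4 * np.pi, n)
        h0 = np.stack([1 + np.sin(t), 1 + np.cos(1.3 * t)])
        e = w0 @ h0
        if noise:
            e = np.clip(e + noise * e.mean() * r.standard_normal(e.shape),
                        0, None)
        return e, w0, h0

    def test_exact_rank2_reconstruction(self):
        e, _, _ = self._rank2()
        syn = extract_synergies(e, k=2, n_restarts=5)
        assert syn.vaf >= 0.999

    def test_vaf_monotone_in_rank(self):
        e, _, _ = self._rank2(noise=0.05)
        vafs = [extract_synergies(e, k=k, n_restarts=5, seed=1).vaf
                for k in (1, 2, 5)]
        assert vafs == sorted(vafs)

    def test_noisy_rank2_recovers_weights(self):
        e, w0, _ = self._rank2(noise=0.05, seed=3)
        syn = extract_synergies(e, k=2, n_restarts=10, seed=2)
        # permutation-matched cosine similarity oracle
        def cos(a, b):
            return a @ b / (np.linalg.norm(a) * np.linalg.norm(b))
        w = syn.weights
        best = max(
            min(cos(w[:, p[0]], w0[:, 0]), cos(w[:, p[1]], w0[:, 1]))
            for p in ([0, 1], [1, 0]))
        assert best >= 0.95

    def test_vaf_target_selects_small_rank(self):
        e, _, _ = self._rank2()
        syn = extract_synergies(e, vaf_target=0.90, n_restarts=3)
        assert syn.k <= 2
        assert syn.vaf >= 0.90

    def test_negative_envelope_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            extract_synergies(np.array([[1.0, -0.5], [0.2, 0.3]]), k=1)

    def test_envelope_container_validates(self):
        with pytest.raises(ValueError, match="nonnegative"):
            Envelope(np.array([[-1.0, 0.0]]), RATE, ("biceps_brachii",))
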