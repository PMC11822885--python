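"""Filtering chain: notch, CAR, FIR delay correction, STFT, epoching."""

import numpy as np
import pytest

import intentdecode as itd
from intentdecode.preprocess import band_power_uncorrected


def sinusoid_recording(freq, fs=500.0, duration=10.0, amp=1.0, n_channels=1):
    t = np.arange(int(duration * fs)) / fs
    x = amp * np.sin(2 * np.pi * freq * t)
    return itd.Recording(np.tile(x, (n_channels, 1)), fs), t


class TestNotch:
    def test_60hz_attenuated_30db(self):
        rec, _ = sinusoid_recording(60.0)
        out = itd.notch_line_noise(rec)
        # compare RMS over the central stretch, away from filter edges
        sl = slice(500, -500)
        ratio = out.samples[0, sl].std() / rec.samples[0, sl].std()
        assert 20 * np.log10(ratio) < -30

    def test_dc_unchanged(self):
        rec = itd.Recording(np.full((1, 5000), 3.7), 500.0)
        out = itd.notch_line_noise(rec)
        assert np.allclose(out.samples, rec.samples, atol=1e-6)

    def test_100hz_amplitude_preserved_within_1pct(self):
        rec, t = sinusoid_recording(100.0)
        out = itd.notch_line_noise(rec)
        # least-squares amplitude of the fitted 100 Hz sinusoid
        basis = np.column_stack([np.sin(2 * np.pi * 100 * t), np.cos(2 * np.pi * 100 * t)])
        coef, *_ = np.linalg.lstsq(basis, out.samples[0], rcond=None)
        assert np.hypot(*coef) == pytest.approx(1.0, rel=0.01)

    def test_harmonic_above_nyquist_rejected(self):
        rec, _ = sinusoid_recording(10.0, fs=500.0)
        with pytest.raises(ValueError, match="300"):
            itd.notch_line_noise(rec, harmonics=(300.0,))


class TestCommonAverageReference:
    def test_hand_example(self):
        rec = itd.Recording(np.array([[1.0, 2.0], [3.0, 4.0]]), 500.0)
        out = itd.common_average_reference(rec)
        assert np.allclose(out.samples, [[-1.0, -1.0], [1.0, 1.0]])

    def test_common_mode_rejection(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((4, 1000))
        x -= x.mean(axis=0)  # zero mean across channels
        rec = itd.Recording(x, 500.0)
        out = itd.common_average_reference(rec)
        assert np.allclose(out.samples, x)
        # adding an identical signal to all channels changes nothing post-CAR
        common = rng.standard_normal(1000)
        out2 = itd.common_average_reference(itd.Recording(x + common, 500.0))
        assert np.allclose(out2.samples, x, atol=1e-12)

    def test_bad_channel_excluded_from_mean_but_referenced(self):
        channels = [itd.ChannelInfo("a"), itd.ChannelInfo("b"), itd.ChannelInfo("c", good=False)]
        x = np.array([[1.0], [3.0], [100.0]])
        out = itd.common_average_reference(itd.Recording(x, 500.0, channels))
        assert np.allclose(out.samples[:, 0], [-1.0, 1.0, 98.0])

    def test_too_few_good_channels(self):
        channels = [itd.ChannelInfo("a"), itd.ChannelInfo("b", good=False)]
        with pytest.raises(ValueError, match="2 good channels"):
            itd.common_average_reference(itd.Recording(np.zeros((2, 10)), 500.0, channels))


class TestFilterDesign:
    @pytest.mark.parametrize(
        "fs,n_expected,delay_ms",
        [(500.0, 200, 199.0), (1000.0, 400, 199.5), (2000.0, 800, 199.75)],
    )
    def test_tap_rule_and_group_delay(self, fs, n_expected, delay_ms):
        spec = itd.design_band_filter(fs, (70.0, 200.0))
        assert spec.n_taps == n_expected
        assert spec.group_delay * 1000 == pytest.approx(delay_ms, abs=1e-9)

    def test_doubling_transition_bandwidth_halves_taps(self):
        a = itd.design_band_filter(500.0, (70.0, 200.0), 10.0)
        b = itd.design_band_filter(500.0, (70.0, 200.0), 20.0)
        assert b.n_taps == a.n_taps // 2
        assert b.group_delay == pytest.approx(a.group_delay / 2, rel=0.01)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist|inside"):
            itd.design_band_filter(500.0, (70.0, 260.0))


def am_recording(fs=500.0, duration=20.0, carrier=100.0, mod=2.0, depth=0.5):
    t = np.arange(int(duration * fs)) / fs
    amp = 1.0 + depth * np.sin(2 * np.pi * mod * t)
    return itd.Recording((amp * np.sin(2 * np.pi * carrier * t))[None, :], fs), amp


def xcorr_lag(a, b, max_lag):
    """Lag (samples) maximizing correlation of a against b."""
    a = a - a.mean()
    b = b - b.mean()
    lags = np.arange(-max_lag, max_lag + 1)
    corr = [np.dot(a[max(0, k):len(a) + min(0, k)], b[max(0, -k):len(b) - max(0, k)])
            for k in lags]
    return int(lags[np.argmax(corr)])


class TestBandPower:
    def test_corrected_envelope_aligns_with_true_modulation(self):
        rec, amp = am_recording()
        spec = itd.design_band_filter(rec.sampling_rate, (70.0, 130.0))
        env = itd.band_power(rec, spec)
        sl = env.valid
        lag = xcorr_lag(env.power[0, sl], (amp**2)[sl], max_lag=150)
        assert abs(lag) <= 1

    def test_uncorrected_envelope_lags_by_group_delay(self):
        rec, amp = am_recording()
        spec = itd.design_band_filter(rec.sampling_rate, (70.0, 130.0))
        env = band_power_uncorrected(rec, spec)
        sl = env.valid
        lag = xcorr_lag(env.power[0, sl], (amp**2)[sl], max_lag=150)
        assert abs(lag - spec.delay_samples) <= 1

    def test_zero_input_zero_envelope(self):
        rec = itd.Recording(np.zeros((1, 5000)), 500.0)
        spec = itd.design_band_filter(500.0, (70.0, 200.0))
        env = itd.band_power(rec, spec)
        assert np.allclose(env.power, 0.0)

    def test_power_nonnegative_and_edges_masked(self, signal_env):
        assert (signal_env.power >= 0).all()
        d = signal_env
        spec = itd.design_band_filter(d.sampling_rate, d.band)
        assert not d.valid[: spec.delay_samples].any()
        assert not d.valid[-spec.delay_samples:].any()
        assert d.valid[spec.delay_samples: -spec.delay_samples].all()

    def test_too_short_record_rejected(self):
        rec = itd.Recording(np.zeros((1, 400)), 500.0)
        spec = itd.design_band_filter(500.0, (70.0, 200.0))
        with pytest.raises(ValueError, match="short"):
            itd.band_power(rec, spec)

    def test_notch_then_band_power_changes_hg_envelope_little(self):
        """60 Hz removal leaves the 70-200 Hz envelope nearly untouched."""
        rng = np.random.default_rng(3)
        x = rng.standard_normal(10000) + 2 * np.sin(2 * np.pi * 60 * np.arange(10000) / 500)
        rec = itd.Recording(x[None, :], 500.0)
        spec = itd.design_band_filter(500.0, (70.0, 200.0))
        a = itd.band_power(rec, spec)
        b = itd.band_power(itd.notch_line_noise(rec, harmonics=(60.0,)), spec)
        sl = a.valid
        rel = np.sqrt(np.mean((a.power[0, sl] - b.power[0, sl]) ** 2)) / np.sqrt(
            np.mean(a.power[0, sl] ** 2)
        )
        assert rel < 0.01


class TestStft:
    def test_white_noise_flat_over_time(self):
        rng = np.random.default_rng(1)
        rec = itd.Recording(rng.standard_normal((1, 20000)), 500.0)
        _, _, logp = itd.stft_power(rec)
        total = logp[0].mean(axis=0)
        assert total.std() < 0.2

    def test_60hz_peak_at_correct_bin(self):
        t = np.arange(20000) / 500.0
        rec = itd.Recording(np.sin(2 * np.pi * 60 * t)[None, :], 500.0)
        freqs, _, logp = itd.stft_power(rec)
        peak_freq = freqs[np.argmax(logp[0].mean(axis=1))]
        assert abs(peak_freq - 60.0) < 2.0

    def test_planted_hg_burst_localized(self):
        rng = np.random.default_rng(2)
        fs = 500.0
        x = rng.standard_normal(int(20 * fs)) * 0.1
        t = np.arange(x.size) / fs
        burst = (t > 10) & (t < 12)
        x[burst] += 5 * np.sin(2 * np.pi * 120 * t[burst])
        freqs, times, logp = itd.stft_power(itd.Recording(x[None, :], fs))
        inside = (times > 10.5) & (times < 11.5)
        outside = (times < 9) | (times > 13)
        row_120 = np.argmin(np.abs(freqs - 120.0))
        row_30 = np.argmin(np.abs(freqs - 30.0))
        assert logp[0, row_120, inside].mean() > logp[0, row_120, outside].mean() + 1.0
        assert abs(logp[0, row_30, inside].mean() - logp[0, row_30, outside].mean()) < 0.5

    def test_step_larger_than_window_rejected(self):
        rec = itd.Recording(np.zeros((1, 5000)), 500.0)
        with pytest.raises(ValueError, match="step"):
            itd.stft_power(rec, window=0.2, step=0.3)


class TestEpoch:
    def test_sample_count_convention(self, signal_env, signal_dataset):
        _, _, events, _ = signal_dataset
        ep = itd.epoch(signal_env, events, align="voice_onset", window=(-1.0, 0.5))
        assert ep.data.shape[2] == 751  # 500 Hz, inclusive endpoints
        assert ep.data.shape[0] == events.n_trials

    def test_zscore_constant_envelope_yields_zeros(self):
        env = itd.BandPowerEnvelope(
            power=np.full((2, 5000), 4.0),
            band=(70.0, 200.0),
            sampling_rate=500.0,
            channels=[itd.ChannelInfo("a"), itd.ChannelInfo("b")],
            valid=np.ones(5000, dtype=bool),
        )
        import pandas as pd

        events = itd.TrialEvents(
            pd.DataFrame(
                dict(
                    trial_id=[0],
                    task=["visual_delay"],
                    stimulus_onset_s=[1.0],
                    stimulus_offset_s=[2.0],
                    go_cue_s=[4.0],
                    voice_onset_s=[5.0],
                    voice_offset_s=[5.5],
                )
            )
        )
        with pytest.warns(RuntimeWarning, match="constant"):
            ep = itd.epoch(env, events, align="voice_onset", window=(-1.0, 0.5), z_score=True)
        assert np.allclose(ep.data, 0.0)

    def test_out_of_bounds_trials_dropped_and_reported(self, signal_env, signal_dataset):
        _, _, events, _ = signal_dataset
        # huge window: early trials fall off the front of the record
        ep = itd.epoch(signal_env, events, align="voice_onset", window=(-6.0, 0.5))
        assert len(ep.dropped_trial_ids) >= 1
        assert ep.data.shape[0] + len(ep.dropped_trial_ids) == events.n_trials

    def test_production_channel_rises_before_zero(self, signal_dataset, signal_epochs):
        _, _, _, truth = signal_dataset
        prod = [i for i, r in enumerate(truth.channel_roles) if r == "production"]
        tr = signal_epochs.data[:, prod, :].mean(axis=(0, 1))
        times = signal_epochs.times
        pre = (times >= -0.2) & (times < 0)
        base = times < -0.5
        assert tr[pre].mean() > tr[base].mean() + 2 * tr[base].std()
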