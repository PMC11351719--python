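import numpy as np
import pandas as pd
import pytest
from scipy import signal

import avcond as av
from avcond.preprocess import (PreprocConfig, bandpass, detect_bad_channels,
                               epoch_and_baseline, interpolate_spherical,
                               reject_amplitude, remove_line_noise, resample,
                               split_phases)

SRATE = 1000.0


def _band_power(x, srate, f0, half=2.0):
    freqs, psd = signal.periodogram(x, fs=srate)
    return psd[(freqs >= f0 - half) & (freqs <= f0 + half)].sum()


class TestBandpass:
    def test_passband_tone_preserved(self):
        t = np.arange(0, 10, 1 / SRATE)
        x = np.sin(2 * np.pi * 10 * t)
        y = bandpass(x, SRATE)
        core = slice(2000, -2000)  # away from edges
        ratio = np.abs(y[core]).max() / np.abs(x[core]).max()
        assert abs(ratio - 1.0) < 0.01

    def test_dc_removed(self):
        x = np.full(20000, 7.3)
        y = bandpass(x, SRATE)
        assert abs(y[5000:-5000].mean()) < 0.05 * 7.3

    def test_cutoff_attenuation_is_3db_single_pass(self):
        # an order-2 Butterworth has |H| = 1/sqrt(2) at its cutoff
        cfg = PreprocConfig()
        for btype, cutoff in (("highpass", cfg.hp_hz), ("lowpass", cfg.lp_hz)):
            sos = signal.butter(cfg.filter_order, cutoff, btype, fs=SRATE,
                                output="sos")
            _, h = signal.sosfreqz(sos, worN=[cutoff], fs=SRATE)
            assert abs(np.abs(h[0]) - 1 / np.sqrt(2)) < 1e-6

    def test_low_srate_rejected(self):
        with pytest.raises(ValueError, match="too low"):
            bandpass(np.zeros(100), 100.0)


class TestLineNoise:
    def test_line_component_removed(self):
        rng = np.random.default_rng(0)
        t = np.arange(0, 4, 1 / SRATE)
        clean = rng.standard_normal(t.size)
        noisy = clean + 5 * np.sin(2 * np.pi * 50 * t + 0.3)
        out = remove_line_noise(noisy, SRATE)
        before = _band_power(noisy, SRATE, 50)
        after = _band_power(out, SRATE, 50)
        assert 10 * np.log10(before / after) >= 20

    def test_harmonic_removed(self):
        rng = np.random.default_rng(1)
        t = np.arange(0, 4, 1 / SRATE)
        noisy = rng.standard_normal(t.size) + 3 * np.sin(2 * np.pi * 100 * t)
        out = remove_line_noise(noisy, SRATE)
        assert 10 * np.log10(_band_power(noisy, SRATE, 100)
                             / _band_power(out, SRATE, 100)) >= 20

    def test_clean_spectrum_untouched(self):
        rng = np.random.default_rng(2)
        t = np.arange(0, 4, 1 / SRATE)
        x = rng.standard_normal(t.size) + np.sin(2 * np.pi * 23 * t)
        out = remove_line_noise(x, SRATE)
        for f0 in (10.0, 23.0, 40.0, 70.0):  # > 5 Hz from any line frequency
            db = 10 * np.log10(_band_power(x, SRATE, f0)
                               / _band_power(out, SRATE, f0))
            assert abs(db) < 1.0


def _epochs_from_array(data, layout, srate=250.0):
    n = data.shape[0]
    meta = pd.DataFrame({"trial_id": range(n), "block": 0,
                         "trial_type": "A1-trial", "visual_outcome": "V1",
                         "audio_onset_ms": 0.0, "visual_onset_ms": 650.0,
                         "iti_ms": 2500.0})
    times = -300.0 + np.arange(data.shape[2]) * 1000.0 / srate
    return av.EpochSet(data, times, srate, layout, meta)


class TestBadChannels:
    def test_independent_noise_channel_flagged(self, layout):
        rng = np.random.default_rng(0)
        common = rng.standard_normal((5, 1, 400))
        data = np.repeat(common, 27, axis=1) + 0.05 * rng.standard_normal(
            (5, 27, 400))
        bad = layout.names.index("C3")
        data[:, bad] = rng.standard_normal((5, 400))
        flagged = detect_bad_channels(_epochs_from_array(data, layout))
        assert flagged == ["C3"]

    def test_shared_source_keeps_all(self, layout):
        rng = np.random.default_rng(1)
        common = rng.standard_normal((5, 1, 400))
        data = np.repeat(common, 27, axis=1) + 0.05 * rng.standard_normal(
            (5, 27, 400))
        assert detect_bad_channels(_epochs_from_array(data, layout)) == []

    def test_flat_channel_flagged(self, layout):
        rng = np.random.default_rng(2)
        common = rng.standard_normal((5, 1, 400))
        data = np.repeat(common, 27, axis=1) + 0.05 * rng.standard_normal(
            (5, 27, 400))
        data[:, layout.names.index("Pz")] = 4.2
        assert "Pz" in detect_bad_channels(_epochs_from_array(data, layout))


class TestInterpolation:
    def test_empty_bad_list_is_identity(self, layout):
        rng = np.random.default_rng(0)
        ep = _epochs_from_array(rng.standard_normal((3, 27, 100)), layout)
        out = interpolate_spherical(ep, [])
        assert np.array_equal(out.data, ep.data)

    def test_smooth_topography_reconstructed(self, layout):
        # dipolar (smooth) spatial pattern: interpolation should recover the
        # corrupted channel to high fidelity
        rng = np.random.default_rng(3)
        direction = np.array([0.3, 0.8, 0.52])
        pattern = layout.pos3d @ direction
        wave = rng.standard_normal((4, 1, 200))
        data = pattern[None, :, None] * wave
        truth = data.copy()
        bad = layout.names.index("C4")
        data[:, bad] = rng.standard_normal((4, 200))
        out = interpolate_spherical(_epochs_from_array(data, layout), ["C4"])
        rec = out.data[:, bad].ravel()
        true = truth[:, bad].ravel()
        r = np.corrcoef(rec, true)[0, 1]
        assert r > 0.8
        rel_rmse = np.sqrt(((rec - true) ** 2).mean()) / np.sqrt(
            (true ** 2).mean())
        assert rel_rmse < 0.2
        # good channels untouched
        good = [i for i in range(27) if i != bad]
        assert np.array_equal(out.data[:, good], data[:, good])

    def test_too_many_bads_rejected(self, layout):
        rng = np.random.default_rng(4)
        ep = _epochs_from_array(rng.standard_normal((2, 27, 50)), layout)
        with pytest.raises(ValueError, match="too many"):
            interpolate_spherical(ep, layout.names[:14])


class TestEpochBaseline:
    def test_baseline_window_mean_is_zero(self, layout):
        rng = np.random.default_rng(0)
        ep = _epochs_from_array(rng.standard_normal((6, 27, 400)), layout)
        out, dropped = epoch_and_baseline(ep)
        bl = out.time_mask(-300.0, 0.0)
        assert np.abs(out.data[..., bl].mean(axis=-1)).max() < 1e-12
        assert dropped == []

    def test_car_zeroes_channel_mean(self, layout):
        rng = np.random.default_rng(1)
        ep = _epochs_from_array(rng.standard_normal((4, 27, 400)), layout)
        out, _ = epoch_and_baseline(ep)
        assert np.abs(out.data.mean(axis=1)).max() < 1e-12

    def test_constant_trial_becomes_zero(self, layout):
        data = np.full((1, 27, 400), 3.7)
        out, _ = epoch_and_baseline(_epochs_from_array(data, layout))
        assert np.allclose(out.data, 0.0)

    def test_epoching_continuous_at_250hz_gives_400_samples(self, layout):
        rng = np.random.default_rng(2)
        cont = rng.standard_normal((27, 5000))
        schedule = pd.DataFrame({
            "trial_id": [0, 1, 2], "block": 0, "trial_type": "A1-trial",
            "visual_outcome": "V1",
            "audio_onset_ms": [1000.0, 5000.0, 19990.0],
            "visual_onset_ms": np.nan, "iti_ms": 2500.0})
        out, dropped = epoch_and_baseline(cont, schedule, layout=layout,
                                          srate=250.0)
        assert out.data.shape == (2, 27, 400)
        assert dropped == [2]  # too close to the recording edge
        assert out.times[0] == -300.0 and out.times[-1] == 1296.0


class TestRejection:
    def test_spike_trial_removed(self, layout):
        rng = np.random.default_rng(0)
        data = 10 * rng.standard_normal((6, 27, 100))
        data[3, 5, 50] = 600.0
        ep = _epochs_from_array(data, layout)
        out, report = reject_amplitude(ep)
        assert out.n_trials == 5
        assert report["rejected_trial_ids"] == [3]
        assert report["fraction_rejected"] == pytest.approx(1 / 6)

    def test_clean_data_untouched(self, layout):
        rng = np.random.default_rng(1)
        ep = _epochs_from_array(10 * rng.standard_normal((6, 27, 100)), layout)
        out, report = reject_amplitude(ep)
        assert out.n_trials == 6 and report["n_rejected"] == 0


class TestPhases:
    def test_nine_trials_split_evenly(self):
        phases = split_phases(["A1"] * 9)
        assert [len(phases[k]) for k in ("initial", "middle", "final")] == [3, 3, 3]

    def test_ten_trials_earliest_largest(self):
        phases = split_phases(["A1"] * 10)
        assert [len(phases[k]) for k in ("initial", "middle", "final")] == [4, 3, 3]

    def test_phases_are_chronological_within_condition(self):
        labels = ["A1", "A2"] * 30
        phases = split_phases(labels)
        assert phases["initial"].max() < phases["final"].min()

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            split_phases(["A1", "A1", "A2", "A2", "A2"])


def test_resample_halves_samples_and_preserves_slow_content(layout):
    t = np.arange(0, 1.6, 1 / 500.0)
    wave = np.sin(2 * np.pi * 5 * (t - 0.3))
    data = np.tile(wave, (2, 27, 1))
    ep = av.EpochSet(data, -300 + t * 1000, 500.0, layout,
                     _epochs_from_array(data, layout, 500.0).meta)
    out = resample(ep, 250.0)
    assert out.data.shape[-1] == 400
    expected = np.sin(2 * np.pi * 5 * (out.times / 1000.0))
    core = slice(20, -20)
    assert np.allclose(out.data[0, 0, core], expected[core], atol=0.01)


def test_full_chain_is_deterministic(noisy_session):
    epochs, _ = noisy_session
    a, _ = av.preprocess_session(epochs)
    b, _ = av.preprocess_session(epochs)
    assert np.array_equal(a.data, b.data)
    assert a.data.shape[0] == epochs.data.shape[0]  # no trials lost here
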