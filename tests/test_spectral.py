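"""Spectrogram, band-pass, and Δ power statistic."""

import numpy as np
import pytest

from oblfp.spectral import (
    BAND_BY_NAME,
    Band,
    bandpass,
    delta_power,
    delta_power_spectrum,
    delta_power_table,
    spectrogram,
)

FS = 1000.0


def _sine(freq, dur=20.0, fs=FS, amp=1.0):
    t = np.arange(int(dur * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


class TestBandpass:
    def test_passband_amplitude_preserved(self):
        x = _sine(9.0)
        y = bandpass(x, "theta", FS)
        seg = slice(2000, -2000)
        assert np.abs(y[seg]).max() == pytest.approx(1.0, rel=0.05)

    def test_stopband_attenuated_40db(self):
        x = _sine(40.0)
        y = bandpass(x, "theta", FS)
        seg = slice(2000, -2000)
        assert np.abs(y[seg]).max() < 10 ** (-40 / 20)

    def test_zero_phase_time_reversal_symmetry(self):
        # filtering a time-reversed impulse gives the reversed response
        x = np.zeros(4001)
        x[2000] = 1.0
        y = bandpass(x, "beta", FS)
        y_rev = bandpass(x[::-1], "beta", FS)
        np.testing.assert_allclose(y, y_rev[::-1], atol=1e-10)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(np.zeros(1000), Band("bad", 100.0, 300.0), 500.0)


class TestSpectrogram:
    def test_sinusoid_power_concentrated_and_parseval(self):
        x = _sine(40.0)
        spec = spectrogram(x, FS)
        mean_db = spec.power_db.mean(axis=0)
        assert spec.freqs[np.argmax(mean_db)] == pytest.approx(40.0, abs=1.0)
        # total power from the PSD matches the signal variance (0.5) within 1%
        df = spec.freqs[1] - spec.freqs[0]
        total = (10 ** (spec.power_db / 10.0)).sum(axis=1).mean() * df
        assert total == pytest.approx(0.5, rel=0.01)

    def test_silent_signal_sits_at_floor(self):
        spec = spectrogram(np.zeros(5000), FS, db_floor=-120.0)
        assert np.all(spec.power_db == -120.0)

    def test_doubled_variance_raises_3db(self, rng):
        x = rng.standard_normal(30000)
        s1 = spectrogram(x, FS)
        s2 = spectrogram(np.sqrt(2.0) * x, FS)
        rise = s2.power_db.mean() - s1.power_db.mean()
        assert rise == pytest.approx(10 * np.log10(2), abs=0.05)

    def test_window_longer_than_signal_rejected(self):
        with pytest.raises(ValueError, match="shorter than window"):
            spectrogram(np.zeros(500), FS, window_s=1.0)


def _stepped_band_signal(rng, band, gain, onset=8.0, dur=18.0):
    from oblfp.simulate import _apply_envelope, _unit_band_noise

    n = int(dur * FS)
    x = _unit_band_noise(rng, n, FS, band)
    env = np.ones((1, n), dtype=np.float32)
    _apply_envelope(env, int(onset * FS), int((onset + 2.5) * FS), gain, 100)
    return x * env[0]


class TestDeltaPower:
    def test_stationary_null_near_zero(self, rng):
        band = BAND_BY_NAME["beta"]
        deltas = []
        for _ in range(30):
            x = _stepped_band_signal(rng, band, 1.0)
            deltas.append(delta_power(spectrogram(x, FS), 8.0, band))
        assert abs(np.mean(deltas)) < 0.3

    def test_amplitude_doubling_recovers_6db(self, rng):
        band = BAND_BY_NAME["beta"]
        deltas = []
        for _ in range(40):
            x = _stepped_band_signal(rng, band, 2.0)
            deltas.append(delta_power(spectrogram(x, FS), 8.0, band))
        assert np.mean(deltas) == pytest.approx(20 * np.log10(2), abs=0.5)

    def test_antisymmetric_under_window_swap(self, rng):
        band = BAND_BY_NAME["low_gamma"]
        x = _stepped_band_signal(rng, band, 2.0)
        spec = spectrogram(x, FS)
        fwd = delta_power(spec, 8.0, band)
        swapped = delta_power(
            spec, 8.0, band,
            response_window_s=(-2.1, -0.6), baseline_window_s=(0.0, 2.0),
        )
        assert swapped == pytest.approx(-fwd, abs=1e-9)

    def test_invariant_to_global_gain(self, rng):
        band = BAND_BY_NAME["theta"]
        x = _stepped_band_signal(rng, band, 2.0)
        d1 = delta_power(spectrogram(x, FS), 8.0, band)
        d2 = delta_power(spectrogram(1000.0 * x, FS), 8.0, band)
        assert d2 == pytest.approx(d1, abs=1e-6)

    def test_insufficient_coverage_names_interval(self):
        spec = spectrogram(np.zeros(3000), FS)
        with pytest.raises(ValueError, match="baseline"):
            delta_power(spec, 0.5, "theta")


class TestDeltaPowerSpectrum:
    def test_band_limited_step_confined_to_band(self, rng):
        band = BAND_BY_NAME["beta"]
        x = _stepped_band_signal(rng, band, 2.0)
        x = x + 0.5 * rng.standard_normal(x.size)  # broadband floor
        df = delta_power_spectrum(spectrogram(x, FS), 8.0)
        in_band = df.query("15 <= freq_hz <= 30")["delta_db"].mean()
        out_band = df.query("freq_hz > 40")["delta_db"].mean()
        assert in_band > 3.0
        assert abs(out_band) < 1.0

    def test_band_partition_consistency(self, rng):
        # mean per-frequency Δ over a band's bins ≈ the band Δ power
        band = BAND_BY_NAME["beta"]
        x = _stepped_band_signal(rng, band, 2.0)
        spec = spectrogram(x, FS)
        band_delta = delta_power(spec, 8.0, band)
        df = delta_power_spectrum(spec, 8.0, freq_range=(band.f_lo, band.f_hi))
        assert df["delta_db"].mean() == pytest.approx(band_delta, abs=0.3)


class TestDeltaPowerTable:
    def test_matches_single_trial_operation(self, small_session):
        # vectorized table path must agree with the per-trial op
        _, bundle, _ = small_session
        table = delta_power_table(bundle, step_s=0.1)
        spec = spectrogram(bundle.lfp.signal[0].astype(float), FS)
        tr = bundle.trials[3]
        expect = delta_power(spec, tr.odorant_onset_s, "beta")
        got = table.query(
            "electrode == 0 and band == 'beta' and trial_index == @tr.trial_index"
        )["delta_db"].item()
        assert got == pytest.approx(expect, abs=1e-6)

    def test_recovers_programmed_contrast(self, small_session):
        _, bundle, _ = small_session
        table = delta_power_table(bundle)
        beta = table.query("band == 'beta'")
        contrast = (
            beta.query("valence == 'Splus'")["delta_db"].mean()
            - beta.query("valence == 'Sminus'")["delta_db"].mean()
        )
        assert contrast == pytest.approx(6.0, abs=1.5)

    def test_high_rate_input_is_decimated(self):
        # same construction at 2 kHz analyzes identically after decimation
        from oblfp.simulate import SimConfig, simulate_session

        cfg = SimConfig(seed=3, n_trials=6, n_electrodes=1, sampling_rate_hz=2000.0)
        bundle, _ = simulate_session(cfg)
        table = delta_power_table(bundle)
        assert table["delta_db"].notna().all()
        assert len(table) == 6 * 4
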