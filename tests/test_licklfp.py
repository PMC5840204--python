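"""Lick-aligned LFP: onset detection, ERP, theta phase, LR-LFP Δ power."""

import numpy as np
import pandas as pd
import pytest

from oblfp.licklfp import (
    delta_auroc_profile,
    detect_lick_onsets,
    lick_theta_phase,
    lick_triggered_average,
    lr_lfp_delta_power,
    theta_peak_times,
)

FS = 1000.0


class TestDetectOnsets:
    def test_clean_pulses_recovered_exactly(self):
        x = np.zeros(5000)
        true = [500, 1500, 3200]
        for i in true:
            x[i : i + 50] = 1.0
        got = detect_lick_onsets(lick_signal=x, fs=FS)
        np.testing.assert_allclose(got, np.asarray(true) / FS, atol=1.5 / FS)

    def test_contact_bounce_merged(self):
        x = np.zeros(2000)
        x[500:520] = 1.0
        x[540:600] = 1.0  # 20 ms later: bounce
        got = detect_lick_onsets(lick_signal=x, fs=FS, debounce_s=0.07)
        assert got.size == 1

    def test_event_list_passthrough_with_debounce(self):
        got = detect_lick_onsets(lick_times=[0.5, 0.52, 0.8])
        np.testing.assert_allclose(got, [0.5, 0.8])

    def test_flat_signal_yields_empty(self):
        assert detect_lick_onsets(lick_signal=np.zeros(100), fs=FS).size == 0

    def test_exactly_one_input_required(self):
        with pytest.raises(ValueError):
            detect_lick_onsets()


class TestLickTriggeredAverage:
    def test_deterministic_wavelet_recovered(self, rng):
        wav = np.hanning(201) * np.sin(2 * np.pi * 8 * np.arange(201) / FS)
        trace = np.zeros(30000)
        onsets = np.arange(1.0, 28.0, 1.0)
        for t in onsets:
            i = int(t * FS)
            trace[i - 100 : i + 101] += wav
        erp = lick_triggered_average(trace, FS, onsets, n_boot=200, seed=0)
        center = slice(400, 601)
        np.testing.assert_allclose(erp.mean[center], wav, atol=1e-9)
        assert np.all(erp.ci_lo <= erp.mean) and np.all(erp.mean <= erp.ci_hi)

    def test_null_noise_zero_in_ci(self, rng):
        trace = rng.standard_normal(60000)
        onsets = rng.uniform(1.0, 58.0, size=60)
        erp = lick_triggered_average(trace, FS, onsets, n_boot=400, seed=1)
        frac_zero_inside = np.mean((erp.ci_lo <= 0) & (0 <= erp.ci_hi))
        assert frac_zero_inside >= 0.9

    def test_linearity_in_the_signal(self, rng):
        trace = rng.standard_normal(20000)
        onsets = rng.uniform(1.0, 18.0, size=20)
        e1 = lick_triggered_average(trace, FS, onsets, n_boot=50, seed=2)
        e3 = lick_triggered_average(3.0 * trace, FS, onsets, n_boot=50, seed=2)
        np.testing.assert_allclose(e3.mean, 3.0 * e1.mean, rtol=1e-12)

    def test_too_few_licks_rejected(self, rng):
        with pytest.raises(ValueError, match="usable licks"):
            lick_triggered_average(rng.standard_normal(5000), FS, [1.0, 2.0], seed=0)

    def test_edge_licks_dropped_and_counted(self, rng):
        trace = rng.standard_normal(5000)
        onsets = [0.1, 1.0, 2.0, 3.0, 3.7, 4.4, 4.95]
        erp = lick_triggered_average(trace, FS, onsets, n_boot=50, seed=0)
        assert erp.n_licks == 5 and erp.n_dropped == 2


class TestThetaPhase:
    def test_licks_at_peaks_of_pure_tone(self):
        t = np.arange(int(30 * FS)) / FS
        trace = np.cos(2 * np.pi * 9.0 * t)  # peaks at multiples of 1/9 s
        onsets = np.arange(1.0, 29.0, 1.0 / 9.0 * 3)
        res = lick_theta_phase(trace, FS, onsets)
        assert res.resultant_length > 0.98
        assert abs(res.circular_mean) < 0.1  # phase 0 at the peak

    def test_uniform_times_unlocked(self, rng):
        from oblfp.simulate import _unit_band_noise
        from oblfp.spectral import BAND_BY_NAME

        trace = _unit_band_noise(rng, int(200 * FS), FS, BAND_BY_NAME["theta"])
        onsets = rng.uniform(1.0, 199.0, size=1000)
        res = lick_theta_phase(trace, FS, onsets)
        assert res.resultant_length < 0.1

    def test_time_shift_invariance(self, rng):
        # shifting LFP and licks together leaves phases unchanged
        trace = rng.standard_normal(40000)
        onsets = rng.uniform(2.0, 30.0, size=50)
        r1 = lick_theta_phase(trace, FS, onsets, t0=0.0)
        r2 = lick_theta_phase(trace, FS, onsets + 5.0, t0=5.0)
        np.testing.assert_allclose(r1.phases, r2.phases, atol=1e-9)

    def test_peak_times_of_pure_tone(self):
        t = np.arange(int(10 * FS)) / FS
        trace = np.cos(2 * np.pi * 9.0 * t)
        peaks = theta_peak_times(trace, FS)
        inner = peaks[(peaks > 1.0) & (peaks < 9.0)]
        frac = (inner * 9.0) % 1.0
        frac = np.minimum(frac, 1.0 - frac)
        assert frac.max() < 0.05  # within 5% of a cycle of true peaks


@pytest.fixture(scope="module")
def theta_session():
    from oblfp.simulate import SimConfig, simulate_session

    cfg = SimConfig(seed=31, n_trials=30, n_electrodes=1, effect_sd_db=0.5)
    cfg.band_effects["theta"].delta_db_splus = 6.0
    bundle, _ = simulate_session(cfg)
    return bundle


class TestLrLfpDeltaPower:
    def test_programmed_theta_effect_detected(self, theta_session):
        from oblfp.roc import auroc_centered

        df = lr_lfp_delta_power(
            theta_session.lfp.signal[0].astype(float),
            FS,
            theta_session.trials,
            "theta",
            lag_s=0.0,
            seed=0,
        ).dropna(subset=["delta_db"])
        pos = df.query("valence == 'Splus'")["delta_db"]
        neg = df.query("valence == 'Sminus'")["delta_db"]
        assert auroc_centered(pos, neg).auroc > 0.3

    def test_lag_parameter_changes_output(self, theta_session):
        kw = dict(fs=FS, bundle_trials=theta_session.trials, band="theta")
        trace = theta_session.lfp.signal[0].astype(float)
        d0 = lr_lfp_delta_power(trace, band="theta", fs=FS,
                                bundle_trials=theta_session.trials, lag_s=0.0, seed=5)
        d3 = lr_lfp_delta_power(trace, band="theta", fs=FS,
                                bundle_trials=theta_session.trials, lag_s=0.3, seed=5)
        assert not np.allclose(
            d0["delta_db"].to_numpy(), d3["delta_db"].to_numpy(), equal_nan=True
        )

    def test_cr_trials_get_surrogate_alignment(self, theta_session):
        trace = theta_session.lfp.signal[0].astype(float)
        df = lr_lfp_delta_power(trace, FS, theta_session.trials, "theta", seed=1)
        cr = df[df["outcome"] == "CR"]
        assert len(cr) > 0
        assert (~cr["excluded"]).all()  # surrogates make CR trials usable


def _cells(values_by_cell):
    out = {}
    for key, vals in values_by_cell.items():
        out[key] = pd.DataFrame(
            {"band": "theta", "lag_s": 0.0, "auroc": np.asarray(vals, dtype=float)}
        )
    return out


class TestDeltaAurocProfile:
    def test_identical_genotypes_give_zero(self, rng):
        vals = rng.normal(0.3, 0.05, 12)
        cells = _cells(
            {
                ("control", "pre"): vals,
                ("control", "laser"): vals + 0.1,
                ("opsin", "pre"): vals,
                ("opsin", "laser"): vals + 0.1,
            }
        )
        prof = delta_auroc_profile(cells, n_boot=100, seed=0)
        assert prof["delta_auroc"].item() == pytest.approx(0.0, abs=1e-12)

    def test_swapping_genotypes_negates(self, rng):
        cells = {
            ("control", "pre"): rng.normal(0.3, 0.05, 10),
            ("control", "laser"): rng.normal(0.3, 0.05, 10),
            ("opsin", "pre"): rng.normal(0.3, 0.05, 10),
            ("opsin", "laser"): rng.normal(0.0, 0.05, 10),
        }
        swapped = {
            (("opsin" if g == "control" else "control"), e): v
            for (g, e), v in cells.items()
        }
        p1 = delta_auroc_profile(_cells(cells), n_boot=50, seed=0)
        p2 = delta_auroc_profile(_cells(swapped), n_boot=50, seed=0)
        assert p2["delta_auroc"].item() == pytest.approx(-p1["delta_auroc"].item())

    def test_silenced_contrast_recovers_minus_a(self, rng):
        a = 0.4
        cells = _cells(
            {
                ("control", "pre"): rng.normal(a, 0.03, 16),
                ("control", "laser"): rng.normal(a, 0.03, 16),
                ("opsin", "pre"): rng.normal(a, 0.03, 16),
                ("opsin", "laser"): rng.normal(0.0, 0.03, 16),
            }
        )
        prof = delta_auroc_profile(cells, n_boot=300, seed=1)
        row = prof.iloc[0]
        assert row["ci_lo"] <= -a <= row["ci_hi"]
        assert row["p_interaction"] < 1e-6

    def test_missing_cell_rejected(self):
        with pytest.raises(ValueError, match="four cells"):
            delta_auroc_profile(_cells({("control", "pre"): [0.1, 0.2]}))
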