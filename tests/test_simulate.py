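"""Synthetic session generator: task structure, licks, effects, determinism."""

import numpy as np
import pytest
from scipy.signal import hilbert
from scipy.special import iv

from oblfp.behavior import classify_trial
from oblfp.io import Outcome, Valence
from oblfp.simulate import (
    SimConfig,
    ThetaPhase,
    _unit_band_noise,
    simulate_lick_train,
    simulate_session,
)
from oblfp.spectral import BAND_BY_NAME


class TestTaskStructure:
    def test_blocks_are_balanced(self):
        cfg = SimConfig(seed=5, n_trials=60, n_electrodes=1)
        bundle, _ = simulate_session(cfg)
        valences = np.array(
            [tr.odorant_valence is Valence.Splus for tr in bundle.trials]
        )
        for b in range(3):
            assert valences[20 * b : 20 * (b + 1)].sum() == 10

    def test_onset_delay_and_duration(self, small_session):
        _, bundle, _ = small_session
        for tr in bundle.trials:
            delay = tr.odorant_onset_s - tr.port_entry_s
            assert 1.0 <= delay <= 1.5
            assert tr.odorant_duration_s == 2.5

    def test_laser_interval_spans_3p5s_from_port_entry(self):
        cfg = SimConfig(seed=5, n_trials=10, n_electrodes=1, laser_enabled=True)
        bundle, _ = simulate_session(cfg)
        for tr in bundle.trials:
            assert tr.laser_on_s == tr.port_entry_s
            assert tr.laser_off_s - tr.laser_on_s == pytest.approx(3.5)

    def test_outcomes_respect_lick_criterion(self, small_session):
        _, bundle, _ = small_session
        for tr in bundle.trials:
            assert classify_trial(tr) == tr.outcome
            if tr.outcome in (Outcome.CR, Outcome.Miss):
                w = [
                    t for t in tr.lick_times_s
                    if tr.odorant_onset_s <= t < tr.odorant_onset_s + 2.0
                ]
                # withheld trials may not satisfy the response criterion
                assert classify_trial(tr) in (Outcome.CR, Outcome.Miss)

    def test_behavioral_trajectory_calibration(self):
        cfg = SimConfig(seed=9, n_trials=80, n_electrodes=1,
                        p_correct_start=0.9, p_correct_end=0.9)
        bundle, _ = simulate_session(cfg)
        correct = np.array(
            [tr.outcome in (Outcome.Hit, Outcome.CR) for tr in bundle.trials]
        )
        tail = correct[-40:]
        # binomial 95% bounds around p = 0.9 at n = 40
        lo, hi = 0.9 - 1.96 * np.sqrt(0.09 / 40), 0.9 + 1.96 * np.sqrt(0.09 / 40)
        assert lo <= tail.mean() <= hi


class TestDeterminism:
    def test_identical_seed_identical_bundle(self):
        cfg = dict(seed=21, n_trials=12, n_electrodes=2)
        b1, t1 = simulate_session(SimConfig(**cfg))
        b2, t2 = simulate_session(SimConfig(**cfg))
        assert b1.lfp.signal.tobytes() == b2.lfp.signal.tobytes()
        for tr1, tr2 in zip(b1.trials, b2.trials):
            assert tr1.lick_times_s == tr2.lick_times_s
        assert t1.realized_delta_db.equals(t2.realized_delta_db)

    def test_different_seed_differs(self):
        b1, _ = simulate_session(SimConfig(seed=1, n_trials=5, n_electrodes=1))
        b2, _ = simulate_session(SimConfig(seed=2, n_trials=5, n_electrodes=1))
        assert b1.lfp.signal.tobytes() != b2.lfp.signal.tobytes()


class TestGroundTruth:
    def test_lick_consistency(self, small_session):
        # every response-window lick in GroundTruth appears in the events
        _, bundle, truth = small_session
        for i, tr in enumerate(bundle.trials):
            assert len(truth.lick_phases[i]) == 0 or truth.respond[i]

    def test_programmed_mean_contrast(self, small_session):
        _, _, truth = small_session
        beta = truth.realized_delta_db.query("band == 'beta'")
        assert beta["delta_db"].max() == pytest.approx(6.0)
        assert beta["delta_db"].min() == pytest.approx(0.0)

    def test_infeasible_band_rejected(self):
        cfg = SimConfig(seed=0, sampling_rate_hz=120.0)
        with pytest.raises(ValueError, match="Nyquist"):
            simulate_session(cfg)

    def test_laser_control_factor_must_be_unity(self):
        cfg = SimConfig(seed=0, laser_effect={"control": 0.5, "opsin": 0.0})
        with pytest.raises(ValueError, match="control"):
            cfg.validate()


def _theta_phase(seed, duration=60.0, fs=1000.0):
    rng = np.random.default_rng(seed)
    n = int(duration * fs)
    theta = _unit_band_noise(rng, n, fs, BAND_BY_NAME["theta"])
    u = np.unwrap(np.angle(hilbert(theta.astype(float))))
    return theta, ThetaPhase(np.arange(n) / fs, u)


class TestLickTrain:
    def test_rate_matches_expectation(self):
        _, phase = _theta_phase(3, duration=120.0)
        rng = np.random.default_rng(0)
        counts = [
            len(simulate_lick_train((t0, t0 + 2.0), 7.0, phase, 2.0, rng)[0])
            for t0 in np.arange(2.0, 110.0, 2.5)
        ]
        assert np.mean(counts) == pytest.approx(14.0, abs=2.0)

    def test_kappa2_resultant_length(self):
        _, phase = _theta_phase(4, duration=120.0)
        times, prog = simulate_lick_train(
            (2.0, 118.0), 7.0, phase, 2.0, np.random.default_rng(1)
        )
        R = np.abs(np.exp(1j * prog).mean())
        assert R == pytest.approx(iv(1, 2.0) / iv(0, 2.0), abs=0.05)

    def test_uniform_phases_when_unlocked(self):
        theta, phase = _theta_phase(5, duration=160.0)
        times, _ = simulate_lick_train(
            (2.0, 158.0), 7.0, phase, 0.0, np.random.default_rng(2)
        )
        measured = phase.wrapped(times)
        assert np.abs(np.exp(1j * measured).mean()) < 0.1

    def test_refractory_enforced(self):
        _, phase = _theta_phase(6)
        for kappa in (0.0, 2.0):
            times, _ = simulate_lick_train(
                (2.0, 58.0), 12.0, phase, kappa, np.random.default_rng(3)
            )
            assert np.diff(times).min() >= 0.07 - 1e-9

    def test_bad_window_rejected(self):
        _, phase = _theta_phase(7, duration=10.0)
        with pytest.raises(ValueError, match="window"):
            simulate_lick_train((5.0, 5.0), 7.0, phase, 1.0, 0)
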