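"""Synthetic go/no-go sessions with programmable LFP band-power effects.

The generator emulates the statistical structure of the recordings the
pipeline is built for, with every effect size programmable:

* trials arrive in 20-trial blocks containing 10 S+ and 10 S− odorants in
  random order; odorant onset falls 1–1.5 s after port entry and lasts
  2.5 s;
* the simulated mouse responds correctly with a per-trial probability that
  ramps linearly across the session (a crude learning curve); a "respond"
  decision yields licking that satisfies the behavioral criterion (one lick
  in each of four 0.5 s intervals from odorant onset), a "withhold"
  decision yields no response-window licks (misses produce no licks, false
  alarms produce S+-like lick trains);
* each electrode's LFP is 1/f-like background noise plus four band-limited
  oscillators (Gaussian noise band-passed to theta/beta/low-gamma/
  high-gamma).  During the odorant each band's amplitude is stepped by a
  programmed per-trial dB change (valence-, learning-, laser- and
  genotype-dependent), with a 100 ms cosine ramp to avoid spectral splatter;
* one shared theta process per session drives both the theta component of
  every electrode (with electrode-specific gain) and lick timing: lick
  phases on that process are von Mises distributed with concentration
  ``theta_lock_kappa``, implementing lick–theta phase locking with a single
  mechanism.

Identical seeds give byte-identical sessions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io import (
    Genotype,
    LfpRecord,
    Outcome,
    SessionBundle,
    SessionMeta,
    TrialEvent,
    Valence,
    ODORANT_LABELS,
)
from .spectral import DEFAULT_BANDS, Band

__all__ = [
    "BandEffect",
    "SimConfig",
    "GroundTruth",
    "simulate_session",
    "simulate_lick_train",
    "ThetaPhase",
    "learning_session_configs",
    "reversal_session_configs",
    "opto_cell_configs",
]

TWO_PI = 2.0 * np.pi


@dataclass
class BandEffect:
    """Programmed odorant-evoked power change for one band.

    ``delta_db_splus`` / ``delta_db_sminus`` are the mean dB changes on
    rewarded / unrewarded trials; ``amplitude_uv`` is the baseline standard
    deviation of the band oscillator in microvolts.
    """

    delta_db_splus: float = 0.0
    delta_db_sminus: float = 0.0
    amplitude_uv: float = 10.0


def default_band_effects() -> dict:
    # Amplitudes fall off with frequency, mimicking the 1/f trend of real
    # LFP; values keep each oscillator's in-band PSD well above background.
    return {
        "theta": BandEffect(0.0, 0.0, 15.0),
        "beta": BandEffect(0.0, 0.0, 10.0),
        "low_gamma": BandEffect(0.0, 0.0, 8.0),
        "high_gamma": BandEffect(0.0, 0.0, 6.0),
    }


@dataclass
class SimConfig:
    seed: int = 0
    n_trials: int = 100
    n_electrodes: int = 16
    sampling_rate_hz: float = 1000.0
    block_size: int = 20
    trial_period_s: float = 7.0
    odorant_duration_s: float = 2.5
    onset_delay_range_s: tuple = (1.0, 1.5)
    # learning curve: P(correct decision), linear from start to end
    p_correct_start: float = 0.95
    p_correct_end: float = 0.95
    band_effects: dict = field(default_factory=default_band_effects)
    effect_sd_db: float = 2.0
    # learning ramp on the programmed effects, linear over trials
    effect_scale_start: float = 1.0
    effect_scale_end: float = 1.0
    # what the odorant-evoked effect is locked to: "value" (the S+/S−
    # label — flips with reward reversal), "identity" (odorant "A" always
    # carries the delta_db_splus effect), or "response" (the animal's
    # respond decision — false alarms then look like hits)
    effect_carrier: str = "value"
    background_sd_uv: float = 10.0
    background_exponent: float = 1.0
    lick_rate_hz: float = 7.0
    theta_lock_kappa: float = 2.0
    lick_refractory_s: float = 0.07
    laser_effect: dict = field(
        default_factory=lambda: {"control": 1.0, "opsin": 1.0}
    )
    laser_duration_s: float = 3.5
    ramp_s: float = 0.1
    electrode_gain_sd: float = 0.1
    # session metadata
    mouse_id: str = "m01"
    genotype: str = "control"
    odorant_pair: str = "APEB"
    session_index: int = 1
    laser_enabled: bool = False
    reward_mapping: str = "A"

    def validate(self) -> None:
        if self.n_trials < 1 or self.n_electrodes < 1:
            raise ValueError("n_trials and n_electrodes must be >= 1")
        if self.block_size % 2:
            raise ValueError("block_size must be even (half S+, half S−)")
        for p in (self.p_correct_start, self.p_correct_end):
            if not 0.0 <= p <= 1.0:
                raise ValueError("p_correct must lie in [0, 1]")
        nyq = self.sampling_rate_hz / 2.0
        for name in self.band_effects:
            band = _band(name)
            if band.f_hi >= nyq:
                raise ValueError(f"band {name} at/above Nyquist {nyq} Hz")
        if abs(self.laser_effect.get("control", 1.0) - 1.0) > 1e-12:
            raise ValueError("laser_effect for the control genotype must be 1.0")
        lo, hi = self.onset_delay_range_s
        if not 0 < lo <= hi:
            raise ValueError("onset_delay_range_s must be 0 < lo <= hi")
        if self.effect_carrier not in ("value", "identity", "response"):
            raise ValueError("effect_carrier must be value, identity or response")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["band_effects"] = {
            k: asdict(v) if isinstance(v, BandEffect) else dict(v)
            for k, v in self.band_effects.items()
        }
        d["onset_delay_range_s"] = list(self.onset_delay_range_s)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "band_effects" in d:
            d["band_effects"] = {
                k: v if isinstance(v, BandEffect) else BandEffect(**v)
                for k, v in d["band_effects"].items()
            }
        if "onset_delay_range_s" in d:
            d["onset_delay_range_s"] = tuple(d["onset_delay_range_s"])
        return cls(**d)


_BANDS = {b.name: b for b in DEFAULT_BANDS}


def _band(name: str) -> Band:
    if name not in _BANDS:
        raise ValueError(f"unknown band {name!r}; options: {sorted(_BANDS)}")
    return _BANDS[name]


@dataclass
class GroundTruth:
    """What the generator actually drew — enables parameter-recovery tests."""

    realized_delta_db: pd.DataFrame  # columns: trial_index, band, delta_db
    respond: np.ndarray
    outcomes: list
    lick_phases: dict  # trial_index -> programmed von Mises phases (response licks)
    electrode_theta_gain: np.ndarray
    theta_band_hz: tuple = (6.0, 12.0)

    def to_json(self, path) -> None:
        payload = {
            "realized_delta_db": self.realized_delta_db.to_dict(orient="list"),
            "respond": self.respond.astype(int).tolist(),
            "outcomes": list(self.outcomes),
            "lick_phases": {str(k): list(map(float, v)) for k, v in self.lick_phases.items()},
            "electrode_theta_gain": self.electrode_theta_gain.tolist(),
            "theta_band_hz": list(self.theta_band_hz),
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


class ThetaPhase:
    """Unwrapped analytic phase of a narrowband process, queryable in time.

    The phase is made monotone (running maximum) before inversion so lick
    placement at a target phase is well defined even where the narrowband
    phase briefly regresses.
    """

    def __init__(self, times: np.ndarray, unwrapped: np.ndarray):
        self.times = times
        self.unwrapped = np.maximum.accumulate(unwrapped)

    def __call__(self, t):
        return np.interp(t, self.times, self.unwrapped)

    def wrapped(self, t):
        return np.angle(np.exp(1j * self(t)))

    def crossing_time(self, target_unwrapped: float) -> float | None:
        u = self.unwrapped
        if target_unwrapped < u[0] or target_unwrapped > u[-1]:
            return None
        i = int(np.searchsorted(u, target_unwrapped))
        if i == 0:
            return float(self.times[0])
        du = u[i] - u[i - 1]
        frac = 0.0 if du <= 0 else (target_unwrapped - u[i - 1]) / du
        return float(self.times[i - 1] + frac * (self.times[i] - self.times[i - 1]))


def simulate_lick_train(
    window: tuple,
    rate_hz: float,
    theta_phase: ThetaPhase,
    kappa: float,
    rng,
    refractory_s: float = 0.07,
) -> tuple[np.ndarray, np.ndarray]:
    """Theta-locked lick times in ``window``; returns (times, programmed phases).

    Each theta cycle in the window carries at most one lick (kept with
    probability ``rate_hz / cycle_rate``) at a phase drawn from a von Mises
    distribution centered on the theta peak with concentration ``kappa``;
    ``kappa = 0`` gives uniform phases.  A refractory period enforces a
    minimum inter-lick interval.
    """
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("window must be non-empty")
    if rate_hz <= 0:
        raise ValueError("rate_hz must be positive")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    if kappa <= 0:
        # no phase locking: licks are a renewal process (refractory dead
        # time + exponential wait) independent of the oscillation, so
        # their theta phases are uniform.  A once-per-cycle construction
        # pruned by the refractory period would leave residual phase
        # structure.
        mean_wait = max(1.0 / rate_hz - refractory_s, 1e-3)
        times, phases = [], []
        t = t0 + float(rng.exponential(mean_wait))
        while t < t1:
            times.append(t)
            phases.append(float(np.angle(np.exp(1j * theta_phase(t)))))
            t += refractory_s + float(rng.exponential(mean_wait))
        return np.asarray(times), np.asarray(phases)

    u0, u1 = float(theta_phase(t0)), float(theta_phase(t1))
    k_lo = int(np.ceil(u0 / TWO_PI))
    k_hi = int(np.floor(u1 / TWO_PI))
    n_cycles = max(k_hi - k_lo + 1, 1)
    cycle_rate = n_cycles / (t1 - t0)
    p_keep = min(1.0, rate_hz / cycle_rate)
    times, phases = [], []
    for k in range(k_lo, k_hi + 1):
        if rng.random() > p_keep:
            continue
        theta = float(rng.vonmises(0.0, kappa)) if kappa > 0 else float(
            rng.uniform(-np.pi, np.pi)
        )
        tc = theta_phase.crossing_time(TWO_PI * k + theta)
        if tc is None or not (t0 <= tc < t1):
            continue
        times.append(tc)
        phases.append(theta)
    order = np.argsort(times)
    out_t, out_p = [], []
    last = -np.inf
    for i in order:
        if times[i] - last >= refractory_s:
            out_t.append(times[i])
            out_p.append(phases[i])
            last = times[i]
    return np.asarray(out_t), np.asarray(out_p)


def _shaped_background(rng, shape, fs: float, exponent: float, sd: float) -> np.ndarray:
    """1/f^exponent Gaussian background, normalized to the target SD per row."""
    white = rng.standard_normal(shape, dtype=np.float32)
    spec = np.fft.rfft(white, axis=-1)
    n = shape[-1] if isinstance(shape, tuple) else shape
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    gain = np.zeros_like(f, dtype=np.float32)
    gain[1:] = f[1:].astype(np.float32) ** np.float32(-exponent / 2.0)
    x = np.fft.irfft(spec * gain, n=n, axis=-1).astype(np.float32)
    s = x.std(axis=-1, keepdims=True)
    return x * np.float32(sd) / np.where(s > 0, s, 1.0)


def _unit_band_noise(rng, shape, fs: float, band: Band) -> np.ndarray:
    """Band-limited Gaussian noise, unit SD per row; rows are independent.

    Synthesized spectrally (complex Gaussian weights under a flat passband
    with half-cosine skirts): equivalent to filtered white noise, cheap for
    long multi-electrode records, and free of filter start-up transients.
    """
    n = shape[-1] if isinstance(shape, tuple) else int(shape)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    skirt = max(0.05 * (band.f_hi - band.f_lo), 0.5)
    gain = np.zeros(f.size, dtype=np.float32)
    core = (f >= band.f_lo) & (f <= band.f_hi)
    gain[core] = 1.0
    lo_sk = (f >= band.f_lo - skirt) & (f < band.f_lo)
    gain[lo_sk] = 0.5 * (1 + np.cos(np.pi * (band.f_lo - f[lo_sk]) / skirt))
    hi_sk = (f > band.f_hi) & (f <= band.f_hi + skirt)
    gain[hi_sk] = 0.5 * (1 + np.cos(np.pi * (f[hi_sk] - band.f_hi) / skirt))
    white = rng.standard_normal(shape, dtype=np.float32)
    x = np.fft.irfft(np.fft.rfft(white, axis=-1) * gain, n=n, axis=-1).astype(
        np.float32
    )
    return x / x.std(axis=-1, keepdims=True)


def _block_valences(rng, n_trials: int, block_size: int) -> np.ndarray:
    """10 S+/10 S− per block (for block_size 20), shuffled within block."""
    out = []
    half = block_size // 2
    while len(out) < n_trials:
        block = np.array([1] * half + [0] * half)
        rng.shuffle(block)
        out.extend(block.tolist())
    return np.asarray(out[:n_trials])


def _apply_envelope(
    env: np.ndarray, i_on: int, i_off: int, gain, n_ramp: int
) -> None:
    """Multiply env rows by a plateau at ``gain`` with cosine ramps at the edges.

    ``env`` is [rows, n_samples]; ``gain`` is scalar or per-row.
    """
    seg = i_off - i_on
    if seg <= 0:
        return
    n_ramp = min(n_ramp, seg // 2)
    gain = np.atleast_1d(np.asarray(gain, dtype=np.float32))[:, None]
    prof = np.ones((gain.shape[0], seg), dtype=np.float32)
    prof *= gain
    if n_ramp > 0:
        ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_ramp) / n_ramp)).astype(
            np.float32
        )
        prof[:, :n_ramp] = 1.0 + (gain - 1.0) * ramp
        prof[:, seg - n_ramp :] = 1.0 + (gain - 1.0) * ramp[::-1]
    env[:, i_on:i_off] *= prof


def simulate_session(config: SimConfig) -> tuple[SessionBundle, GroundTruth]:
    """Generate one session; identical config (incl. seed) => identical bundle."""
    config.validate()
    fs = config.sampling_rate_hz
    n_tr = config.n_trials
    ss = np.random.SeedSequence(config.seed)
    r_beh, r_eff, r_lick, r_sig, r_gain = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    # --- trial schedule -------------------------------------------------
    valence_is_plus = _block_valences(r_beh, n_tr, config.block_size)
    port_entry = 4.0 + config.trial_period_s * np.arange(n_tr)
    lo, hi = config.onset_delay_range_s
    onset = port_entry + r_beh.uniform(lo, hi, size=n_tr)
    duration = float(n_tr * config.trial_period_s + 4.0)
    n_samp = int(round(duration * fs))

    # --- behavioral decisions -------------------------------------------
    p_correct = np.linspace(config.p_correct_start, config.p_correct_end, n_tr)
    correct = r_beh.random(n_tr) < p_correct
    respond = np.where(valence_is_plus.astype(bool), correct, ~correct)
    outcomes = [
        (Outcome.Hit if r else Outcome.Miss)
        if v
        else (Outcome.FA if r else Outcome.CR)
        for v, r in zip(valence_is_plus.astype(bool), respond)
    ]

    # --- programmed per-trial band effects ------------------------------
    scale = np.linspace(config.effect_scale_start, config.effect_scale_end, n_tr)
    laser_factor = (
        config.laser_effect.get(str(Genotype(config.genotype).value), 1.0)
        if config.laser_enabled
        else 1.0
    )
    a_label, b_label = ODORANT_LABELS
    is_odor_a = np.where(
        valence_is_plus.astype(bool),
        config.reward_mapping == a_label,
        config.reward_mapping != a_label,
    )
    gt_rows = []
    delta_db = {}  # band -> [n_electrodes, n_trials] realized dB changes
    carrier = {
        "value": valence_is_plus.astype(bool),
        "identity": is_odor_a,
        "response": respond,
    }[config.effect_carrier]
    for name, eff in config.band_effects.items():
        raw = np.where(carrier, eff.delta_db_splus, eff.delta_db_sminus)
        adj = eff.delta_db_sminus + laser_factor * (raw - eff.delta_db_sminus)
        mean_d = scale * adj
        # trial-to-trial variability is drawn independently per electrode:
        # electrodes are then exchangeable analysis units under a null
        d = mean_d[None, :] + r_eff.normal(
            0.0, config.effect_sd_db, size=(config.n_electrodes, n_tr)
        )
        delta_db[name] = d
        for i in range(n_tr):
            gt_rows.append(
                {"trial_index": i, "band": name, "delta_db": float(mean_d[i])}
            )

    # --- shared theta process and lick trains ---------------------------
    theta_band = _band("theta")
    theta_unit = _unit_band_noise(r_sig, n_samp, fs, theta_band)
    phase_unwrapped = np.unwrap(np.angle(sps.hilbert(theta_unit)))
    t_axis = np.arange(n_samp) / fs
    theta_phase = ThetaPhase(t_axis, phase_unwrapped)

    response_end = 2.2  # covers the four 0.5 s criterion intervals
    lick_times: list[np.ndarray] = []
    lick_phases: dict[int, np.ndarray] = {}
    for i in range(n_tr):
        init_t, _ = simulate_lick_train(
            (port_entry[i] + 0.05, onset[i] - 0.1),
            6.0,
            theta_phase,
            config.theta_lock_kappa,
            r_lick,
            config.lick_refractory_s,
        )
        if respond[i]:
            resp_t, resp_p = simulate_lick_train(
                (onset[i], onset[i] + response_end),
                config.lick_rate_hz,
                theta_phase,
                config.theta_lock_kappa,
                r_lick,
                config.lick_refractory_s,
            )
            # guarantee the behavioral criterion: one lick per 0.5 s interval
            for k in range(4):
                w0, w1 = onset[i] + 0.5 * k, onset[i] + 0.5 * (k + 1)
                if not np.any((resp_t >= w0) & (resp_t < w1)):
                    theta_draw = float(r_lick.vonmises(0.0, max(config.theta_lock_kappa, 1e-6)))
                    k_cyc = int(np.ceil((theta_phase(w0) - theta_draw) / TWO_PI))
                    tc = theta_phase.crossing_time(TWO_PI * k_cyc + theta_draw)
                    if tc is None or not (w0 <= tc < w1):
                        tc = 0.5 * (w0 + w1)
                        theta_draw = float(theta_phase.wrapped(tc))
                    resp_t = np.append(resp_t, tc)
                    resp_p = np.append(resp_p, theta_draw)
            order = np.argsort(resp_t)
            resp_t, resp_p = resp_t[order], resp_p[order]
        else:
            resp_t = np.empty(0)
            resp_p = np.empty(0)
        all_t = np.unique(np.concatenate([init_t, resp_t]))
        lick_times.append(all_t)
        lick_phases[i] = resp_p

    # --- signals ---------------------------------------------------------
    def band_envelope(name: str, e0: int, e1: int) -> np.ndarray:
        env = np.ones((e1 - e0, n_samp), dtype=np.float32)
        gains = 10.0 ** (delta_db[name][e0:e1] / 20.0)
        for i in range(n_tr):
            i_on = int(round(onset[i] * fs))
            i_off = min(int(round((onset[i] + config.odorant_duration_s) * fs)), n_samp)
            _apply_envelope(env, i_on, i_off, gains[:, i], n_ramp)
        return env

    n_ramp = int(round(config.ramp_s * fs))
    theta_gain = np.maximum(
        0.1, 1.0 + r_gain.normal(0.0, config.electrode_gain_sd, size=config.n_electrodes)
    )
    signal = np.empty((config.n_electrodes, n_samp), dtype=np.float32)
    theta_amp = config.band_effects.get("theta", BandEffect()).amplitude_uv
    # every electrode carries the session's shared theta *phase* (this is
    # what licks lock to), but with an electrode-private stochastic
    # amplitude, so theta power fluctuations — like those of the other
    # bands — are independent across electrodes
    theta_carrier = np.cos(phase_unwrapped).astype(np.float32)
    chunk = 16  # electrodes per vectorized batch (memory/speed trade-off)
    for e0 in range(0, config.n_electrodes, chunk):
        e1 = min(e0 + chunk, config.n_electrodes)
        x = _shaped_background(
            r_sig, (e1 - e0, n_samp), fs, config.background_exponent,
            config.background_sd_uv,
        )
        if "theta" in config.band_effects:
            own = _unit_band_noise(r_sig, (e1 - e0, n_samp), fs, theta_band)
            amp = np.abs(sps.hilbert(own, axis=-1)).astype(np.float32)
            comp = amp * theta_carrier
            comp /= comp.std(axis=-1, keepdims=True)
            x += (
                theta_gain[e0:e1, None].astype(np.float32)
                * np.float32(theta_amp)
                * band_envelope("theta", e0, e1)
                * comp
            )
        for name, eff in config.band_effects.items():
            if name == "theta":
                continue
            comp = _unit_band_noise(r_sig, (e1 - e0, n_samp), fs, _band(name))
            x += eff.amplitude_uv * band_envelope(name, e0, e1) * comp
        signal[e0:e1] = x.astype(np.float32)

    # --- assemble --------------------------------------------------------
    meta = SessionMeta(
        mouse_id=config.mouse_id,
        genotype=Genotype(config.genotype),
        odorant_pair=config.odorant_pair,
        session_index=config.session_index,
        sampling_rate_hz=fs,
        n_electrodes=config.n_electrodes,
        laser_enabled=config.laser_enabled,
        reward_mapping=config.reward_mapping,
    )
    trials = []
    for i in range(n_tr):
        trials.append(
            TrialEvent(
                trial_index=i,
                port_entry_s=float(port_entry[i]),
                odorant_onset_s=float(onset[i]),
                odorant_valence=Valence.Splus if valence_is_plus[i] else Valence.Sminus,
                odorant_duration_s=config.odorant_duration_s,
                lick_times_s=lick_times[i].tolist(),
                laser_on_s=float(port_entry[i]) if config.laser_enabled else None,
                laser_off_s=(
                    float(port_entry[i] + config.laser_duration_s)
                    if config.laser_enabled
                    else None
                ),
                outcome=outcomes[i],
            )
        )
    bundle = SessionBundle(
        meta=meta,
        lfp=LfpRecord(signal=signal, sampling_rate_hz=fs, t0=0.0),
        trials=trials,
    )
    bundle.validate()
    truth = GroundTruth(
        realized_delta_db=pd.DataFrame(gt_rows),
        respond=respond,
        outcomes=[o.value for o in outcomes],
        lick_phases=lick_phases,
        electrode_theta_gain=theta_gain,
        theta_band_hz=(theta_band.f_lo, theta_band.f_hi),
    )
    return bundle, truth


# --- scenario builders ----------------------------------------------------
# These encode the study designs the figure-level analyses expect: a
# two-session learning pair, a forward/reversed reward pair, and the
# genotype x laser 2x2.  Sizes are desk-scale defaults; every field can be
# overridden.


def _with_effects(cfg: SimConfig, d_plus: float, d_minus: float, bands=None) -> SimConfig:
    bands = bands or list(cfg.band_effects)
    for name in bands:
        eff = cfg.band_effects[name]
        eff.delta_db_splus = d_plus
        eff.delta_db_sminus = d_minus
    return cfg


def learning_session_configs(
    seed: int,
    n_trials: int = 60,
    n_electrodes: int = 16,
    contrast_db: float = 6.0,
    effect_sd_db: float = 2.0,
    mouse_id: str = "m01",
) -> list[SimConfig]:
    """First (naive, effect ramping in) and last (proficient) sessions."""
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2)]
    first = SimConfig(
        seed=seeds[0],
        n_trials=n_trials,
        n_electrodes=n_electrodes,
        effect_sd_db=effect_sd_db,
        p_correct_start=0.5,
        p_correct_end=0.85,
        effect_scale_start=0.0,
        effect_scale_end=1.0,
        mouse_id=mouse_id,
        session_index=1,
    )
    last = SimConfig(
        seed=seeds[1],
        n_trials=n_trials,
        n_electrodes=n_electrodes,
        effect_sd_db=effect_sd_db,
        p_correct_start=0.9,
        p_correct_end=0.95,
        effect_scale_start=1.0,
        effect_scale_end=1.0,
        mouse_id=mouse_id,
        session_index=2,
    )
    return [
        _with_effects(c, contrast_db, 0.0) for c in (first, last)
    ]


def reversal_session_configs(
    seed: int,
    value_locked: bool = True,
    n_trials: int = 60,
    n_electrodes: int = 16,
    d_plus: float = 4.0,
    d_minus: float = -1.0,
    mouse_id: str = "m01",
) -> tuple[SimConfig, SimConfig]:
    """Forward (odorant A rewarded) and reversed (odorant B rewarded) sessions.

    ``value_locked=False`` ties the effects to the chemical (odorant A) in
    both sessions — the control construction in which no polarity flip
    should be detected.
    """
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2)]
    common = dict(
        n_trials=n_trials,
        n_electrodes=n_electrodes,
        p_correct_start=0.9,
        p_correct_end=0.95,
        effect_carrier="value" if value_locked else "identity",
        odorant_pair="EAPA",
        mouse_id=mouse_id,
    )
    fwd = _with_effects(
        SimConfig(seed=seeds[0], session_index=1, reward_mapping="A", **common),
        d_plus,
        d_minus,
    )
    rev = _with_effects(
        SimConfig(seed=seeds[1], session_index=2, reward_mapping="B", **common),
        d_plus,
        d_minus,
    )
    return fwd, rev


def opto_cell_configs(
    seed: int,
    laser_effect_opsin: float = 0.0,
    n_mice: int = 2,
    n_trials: int = 30,
    n_electrodes: int = 16,
    contrast_db: float = 6.0,
) -> dict:
    """Genotype x laser design: genotype -> per-mouse [pre_cfg, laser_cfg].

    ``pre`` sessions are proficient, laser off; ``laser`` sessions have the
    laser on for 3.5 s from port entry on every trial.  The laser scales the
    programmed S+/S− contrast by ``laser_effect[genotype]`` (control: 1,
    opsin: configurable; 0 silences the contrast entirely).  Several mice
    per genotype give the analysis independent trial draws, as pooling
    electrodes across animals did in the original design.
    """
    ss = np.random.SeedSequence(seed)
    out = {"control": [], "opsin": []}
    for genotype in ("control", "opsin"):
        for m in range(n_mice):
            pair = []
            for epoch in ("pre", "laser"):
                child = ss.spawn(1)[0]
                cfg = SimConfig(
                    seed=int(child.generate_state(1)[0] % (2**31)),
                    n_trials=n_trials,
                    n_electrodes=n_electrodes,
                    p_correct_start=0.9,
                    p_correct_end=0.95,
                    mouse_id=f"{genotype}_{m:02d}",
                    genotype=genotype,
                    session_index=1 if epoch == "pre" else 2,
                    laser_enabled=(epoch == "laser"),
                    laser_effect={"control": 1.0, "opsin": laser_effect_opsin},
                )
                pair.append(_with_effects(cfg, contrast_db, 0.0))
            out[genotype].append(pair)
    return out
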