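"""Lick-aligned LFP: event-related averages, theta phase of licks, LR-LFP Δ power.

The lick-related LFP (LR-LFP) is the raw LFP averaged in a ±0.5 s window
locked to lick onsets.  Its band power, measured by a sliding 1 s window at
a chosen lag from lick onset and baseline-subtracted, yields a per-trial
score (LR-LFP Δ power) that feeds the same auROC machinery as the plain
odorant-evoked Δ power.

Baseline construction: trials without usable licks in a window (correct
rejections withhold licking by design, and no trial licks during the
pre-odorant baseline) are aligned on *surrogate events* placed at theta
phases drawn from the trial's own lick-phase distribution when licks exist,
or at theta peaks otherwise — so the during-vs-baseline subtraction
compares lick-phase-locked power with like-aligned baseline power.  This is
a documented convention (see the methods note), isolated in
:func:`surrogate_events`.

Phase convention: the theta phase of an event is the angle of the analytic
signal of the zero-phase 6–12 Hz filtered LFP at the event sample; 0 at the
oscillation peak, increasing with time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from scipy.signal import hilbert

from .io import SessionBundle
from .roc import auroc_centered
from .resampling import interaction_anova
from .roc import fdr_correct
from .spectral import BASELINE_WINDOW_S, as_band, bandpass, spectrogram
from .simulate import ThetaPhase

__all__ = [
    "LickErp",
    "PhaseResult",
    "detect_lick_onsets",
    "lick_triggered_average",
    "lick_theta_phase",
    "theta_peak_times",
    "surrogate_events",
    "lr_lfp_delta_power",
    "lr_lfp_auroc_table",
    "delta_auroc_profile",
]

THETA = (6.0, 12.0)
ODORANT_LICK_WINDOW_S = 2.0  # licks counted for this long after odorant onset
MIN_LICKS = 5


def detect_lick_onsets(
    lick_signal: np.ndarray | None = None,
    fs: float | None = None,
    t0: float = 0.0,
    lick_times: np.ndarray | None = None,
    debounce_s: float = 0.07,
) -> np.ndarray:
    """Lick onset times from a contact signal or an event list.

    Continuous input: rising crossings of the half-range threshold, merged
    within the debounce window (contact bounce).  Event-list input: sorted
    pass-through with debounce merging.  An empty result is allowed.
    """
    if (lick_signal is None) == (lick_times is None):
        raise ValueError("provide exactly one of lick_signal or lick_times")
    if lick_signal is not None:
        if fs is None:
            raise ValueError("fs is required with a continuous lick signal")
        x = np.asarray(lick_signal, dtype=float)
        lo, hi = x.min(), x.max()
        if hi <= lo:
            return np.empty(0)
        above = x > (lo + hi) / 2.0
        rising = np.flatnonzero(~above[:-1] & above[1:]) + 1
        candidates = t0 + rising / fs
    else:
        candidates = np.sort(np.asarray(lick_times, dtype=float))
    out = []
    last = -np.inf
    for t in candidates:
        if t - last >= debounce_s:
            out.append(t)
            last = t
    return np.asarray(out)


@dataclass
class LickErp:
    """Lick-onset-triggered mean LFP with bootstrap confidence band."""

    lags: np.ndarray
    mean: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    n_licks: int
    n_dropped: int = 0


def _snippets(
    trace: np.ndarray, fs: float, t0: float, onsets: np.ndarray, pre: float, post: float
) -> tuple[np.ndarray, int]:
    n_pre = int(round(pre * fs))
    n_post = int(round(post * fs))
    rows = []
    dropped = 0
    for t in np.asarray(onsets, dtype=float):
        i = int(round((t - t0) * fs))
        if i - n_pre < 0 or i + n_post + 1 > trace.size:
            dropped += 1
            continue
        rows.append(trace[i - n_pre : i + n_post + 1])
    if not rows:
        return np.empty((0, n_pre + n_post + 1)), dropped
    return np.asarray(rows), dropped


def lick_triggered_average(
    trace: np.ndarray,
    fs: float,
    onsets,
    t0: float = 0.0,
    pre_s: float = 0.5,
    post_s: float = 0.5,
    n_boot: int = 1000,
    seed: int | None = None,
    ci_percent: float = 95.0,
) -> LickErp:
    """Mean LFP across lick-locked snippets with a percentile-bootstrap CI.

    Licks whose window leaves the record are dropped (and counted);
    resampling is over licks, deterministic given the seed.
    """
    snip, dropped = _snippets(np.asarray(trace, dtype=float), fs, t0, onsets, pre_s, post_s)
    if snip.shape[0] < MIN_LICKS:
        raise ValueError(
            f"need >= {MIN_LICKS} usable licks, have {snip.shape[0]} "
            f"({dropped} dropped at record edges)"
        )
    mean = snip.mean(axis=0)
    rng = np.random.default_rng(seed)
    n = snip.shape[0]
    boots = np.empty((n_boot, snip.shape[1]))
    for b in range(n_boot):
        boots[b] = snip[rng.integers(0, n, size=n)].mean(axis=0)
    alpha = (100.0 - ci_percent) / 2.0
    ci_lo = np.percentile(boots, alpha, axis=0)
    ci_hi = np.percentile(boots, 100.0 - alpha, axis=0)
    # percentile bootstrap can graze the sample mean; keep the band honest
    ci_lo = np.minimum(ci_lo, mean)
    ci_hi = np.maximum(ci_hi, mean)
    n_pre = int(round(pre_s * fs))
    n_post = int(round(post_s * fs))
    lags = np.arange(-n_pre, n_post + 1) / fs
    return LickErp(lags=lags, mean=mean, ci_lo=ci_lo, ci_hi=ci_hi, n_licks=n, n_dropped=dropped)


@dataclass
class PhaseResult:
    phases: np.ndarray  # wrapped to [-pi, pi)
    circular_mean: float
    resultant_length: float

    @property
    def n(self) -> int:
        return self.phases.size


def _theta_analytic(trace: np.ndarray, fs: float, band=THETA) -> np.ndarray:
    return hilbert(bandpass(trace, band, fs))


def lick_theta_phase(
    trace: np.ndarray,
    fs: float,
    onsets,
    t0: float = 0.0,
    band=THETA,
) -> PhaseResult:
    """Theta phase of each lick onset, with circular mean and resultant length R."""
    onsets = np.asarray(onsets, dtype=float)
    if onsets.size < MIN_LICKS:
        raise ValueError(f"need >= {MIN_LICKS} licks, have {onsets.size}")
    analytic = _theta_analytic(np.asarray(trace, dtype=float), fs, band)
    idx = np.round((onsets - t0) * fs).astype(int)
    idx = idx[(idx >= 0) & (idx < analytic.size)]
    phases = np.angle(analytic[idx])
    z = np.exp(1j * phases).mean()
    return PhaseResult(
        phases=phases,
        circular_mean=float(np.angle(z)),
        resultant_length=float(np.abs(z)),
    )


def theta_peak_times(
    trace: np.ndarray, fs: float, t0: float = 0.0, band=THETA
) -> np.ndarray:
    """Times of theta oscillation peaks (analytic phase rising through 0)."""
    ph = np.angle(_theta_analytic(np.asarray(trace, dtype=float), fs, band))
    d = np.diff(ph)
    crossings = np.flatnonzero((ph[:-1] < 0) & (ph[1:] >= 0) & (d > 0) & (d < np.pi))
    return t0 + (crossings + 1) / fs


def surrogate_events(
    trace: np.ndarray,
    fs: float,
    window: tuple,
    n_events: int,
    t0: float = 0.0,
    phase_pool: np.ndarray | None = None,
    rng=None,
    band=THETA,
) -> np.ndarray:
    """Alignment events inside ``window`` at lick-like theta phases.

    Phases are drawn from ``phase_pool`` (a trial's real lick phases) when
    given, otherwise events sit at theta peaks (phase 0).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    analytic = _theta_analytic(np.asarray(trace, dtype=float), fs, band)
    unwrapped = np.unwrap(np.angle(analytic))
    times = t0 + np.arange(trace.size) / fs
    phase = ThetaPhase(times, unwrapped)
    w0, w1 = window
    u0, u1 = float(phase(w0)), float(phase(w1))
    cycles = np.arange(int(np.ceil(u0 / (2 * np.pi))), int(np.floor(u1 / (2 * np.pi))) + 1)
    if cycles.size == 0:
        return np.empty(0)
    if cycles.size > n_events:
        cycles = np.sort(rng.choice(cycles, size=n_events, replace=False))
    out = []
    for k in cycles:
        target = 0.0 if phase_pool is None or len(phase_pool) == 0 else float(
            rng.choice(np.asarray(phase_pool))
        )
        tc = phase.crossing_time(2 * np.pi * k + target)
        if tc is not None and w0 <= tc < w1:
            out.append(tc)
    return np.asarray(out)


def _event_band_power_db(
    trace: np.ndarray,
    fs: float,
    t0: float,
    events: np.ndarray,
    band,
    lag_s: float,
    span_s: float = 1.0,
) -> float | None:
    """Band power (dB) of the event-locked average at ``lag_s`` from onset.

    The event-locked average is built over ``[-span, +span]`` s so a 1 s
    sliding window centered at any lag in ``[-(span-0.5), span-0.5]`` is
    fully supported.
    """
    snip, _ = _snippets(trace, fs, t0, events, span_s, span_s)
    if snip.shape[0] < 1:
        return None
    erp = snip.mean(axis=0)
    spec = spectrogram(erp, fs, window_s=1.0, step_s=0.1, t0=-span_s)
    band = as_band(band)
    i_t = int(np.argmin(np.abs(spec.times - lag_s)))
    if abs(spec.times[i_t] - lag_s) > 0.1:
        return None
    fm = (spec.freqs >= band.f_lo) & (spec.freqs <= band.f_hi)
    return float(spec.power_db[i_t, fm].mean())


def lr_lfp_delta_power(
    trace: np.ndarray,
    fs: float,
    bundle_trials,
    band,
    lag_s: float = 0.3,
    t0: float = 0.0,
    seed: int | None = None,
    use_sparse_licks: bool = True,
) -> pd.DataFrame:
    """Per-trial LR-LFP Δ power: lick-locked band power during odorant minus
    surrogate-aligned band power in the pre-odorant baseline.

    For each trial the during-odorant alignment events are the trial's licks
    in the 2 s odorant window (trials without licks — correct rejections and
    misses — get surrogate theta-locked events); baseline events are
    surrogates in the −2.1..−0.6 s window at the trial's lick-phase density.
    Trials with no usable alignment events are flagged excluded.
    """
    rng = np.random.default_rng(seed)
    trace = np.asarray(trace, dtype=float)
    rows = []
    for tr in bundle_trials:
        onset = tr.odorant_onset_s
        licks = np.asarray(
            [t for t in tr.lick_times_s if onset <= t < onset + ODORANT_LICK_WINDOW_S]
        )
        phase_pool = None
        if licks.size and use_sparse_licks:
            pool_res = lick_theta_phase(trace, fs, licks, t0=t0) if licks.size >= MIN_LICKS else None
            phase_pool = pool_res.phases if pool_res is not None else None
            during = licks
        else:
            during = np.empty(0)
        if during.size == 0:
            during = surrogate_events(
                trace, fs, (onset, onset + ODORANT_LICK_WINDOW_S), 14, t0=t0, rng=rng
            )
        base_window = (onset + BASELINE_WINDOW_S[0], onset + BASELINE_WINDOW_S[1])
        baseline = surrogate_events(
            trace, fs, base_window, max(during.size, 1), t0=t0,
            phase_pool=phase_pool, rng=rng,
        )
        p_during = _event_band_power_db(trace, fs, t0, during, band, lag_s)
        p_base = _event_band_power_db(trace, fs, t0, baseline, band, lag_s)
        excluded = p_during is None or p_base is None
        rows.append(
            {
                "trial_index": tr.trial_index,
                "delta_db": np.nan if excluded else p_during - p_base,
                "n_events": int(during.size),
                "excluded": excluded,
                "valence": tr.odorant_valence.value,
                "outcome": None if tr.outcome is None else tr.outcome.value,
            }
        )
    return pd.DataFrame(rows)


def lr_lfp_auroc_table(
    bundle: SessionBundle,
    bands,
    lags,
    contrast: str = "hit_cr",
    seed: int | None = None,
) -> pd.DataFrame:
    """Per (electrode, band, lag) centered auROC of LR-LFP Δ power."""
    from .roc import CONTRASTS

    col, pos_label, neg_label = CONTRASTS[contrast]
    fs = bundle.lfp.sampling_rate_hz
    rows = []
    ss = np.random.SeedSequence(seed)
    for e in range(bundle.lfp.n_electrodes):
        trace = bundle.lfp.signal[e].astype(float)
        child = np.random.default_rng(ss.spawn(1)[0])
        for band in bands:
            for lag in lags:
                df = lr_lfp_delta_power(
                    trace,
                    fs,
                    bundle.trials,
                    band,
                    lag_s=lag,
                    t0=bundle.lfp.t0,
                    seed=int(child.integers(2**31)),
                )
                df = df.dropna(subset=["delta_db"])
                pos = df.loc[df[col] == pos_label, "delta_db"].to_numpy()
                neg = df.loc[df[col] == neg_label, "delta_db"].to_numpy()
                if pos.size < 2 or neg.size < 2:
                    continue
                res = auroc_centered(pos, neg, label_pair=contrast)
                rows.append(
                    {
                        "electrode": e,
                        "band": as_band(band).name,
                        "lag_s": lag,
                        "auroc": res.auroc,
                        "p_value": res.p_value,
                        "n_pos": res.n_pos,
                        "n_neg": res.n_neg,
                    }
                )
    return pd.DataFrame(rows)


def delta_auroc_profile(
    auroc_cells: dict,
    n_boot: int = 1000,
    seed: int | None = None,
    q: float = 0.05,
    value_col: str = "auroc",
    grid_cols: tuple = ("band", "lag_s"),
) -> pd.DataFrame:
    """Genotype contrast of the laser-induced auROC change, per band x lag.

    ``auroc_cells`` maps ``(genotype, epoch)`` — genotypes ``control`` /
    ``opsin``, epochs ``pre`` / ``laser`` — to a frame with per-electrode
    auROC values and the grid columns.  For each grid point:

    ``delta_auroc = (mean_laser − mean_pre)_opsin − (mean_laser − mean_pre)_control``

    with a percentile bootstrap CI over electrodes and the genotype x laser
    interaction p-value from a two-way ANOVA on the per-electrode values;
    the band x lag grid is FDR-corrected.  Swapping the genotype labels
    negates the profile exactly; identical genotype groups give 0.
    """
    required = {("control", "pre"), ("control", "laser"), ("opsin", "pre"), ("opsin", "laser")}
    if set(auroc_cells) != required:
        raise ValueError(f"need exactly the four cells {sorted(required)}")
    rng = np.random.default_rng(seed)
    grid = sorted(
        set().union(*[set(map(tuple, df[list(grid_cols)].to_numpy())) for df in auroc_cells.values()])
    )
    rows = []
    for point in grid:
        cell_vals = {}
        ok = True
        for key, df in auroc_cells.items():
            m = np.ones(len(df), dtype=bool)
            for c, v in zip(grid_cols, point):
                m &= df[c].to_numpy() == v
            vals = df.loc[m, value_col].to_numpy(dtype=float)
            if vals.size == 0:
                ok = False
            cell_vals[key] = vals
        if not ok:
            continue
        change = {
            g: cell_vals[(g, "laser")].mean() - cell_vals[(g, "pre")].mean()
            for g in ("control", "opsin")
        }
        delta = change["opsin"] - change["control"]
        boots = np.empty(n_boot)
        for b in range(n_boot):
            means = {}
            for key, vals in cell_vals.items():
                means[key] = vals[rng.integers(0, vals.size, size=vals.size)].mean()
            boots[b] = (means[("opsin", "laser")] - means[("opsin", "pre")]) - (
                means[("control", "laser")] - means[("control", "pre")]
            )
        values = np.concatenate([cell_vals[k] for k in sorted(cell_vals)])
        genotype = np.concatenate(
            [[k[0]] * cell_vals[k].size for k in sorted(cell_vals)]
        )
        laser = np.concatenate([[k[1]] * cell_vals[k].size for k in sorted(cell_vals)])
        inter = interaction_anova(values, genotype, laser)
        rows.append(
            dict(zip(grid_cols, point))
            | {
                "delta_auroc": float(delta),
                "ci_lo": float(np.percentile(boots, 2.5)),
                "ci_hi": float(np.percentile(boots, 97.5)),
                "p_interaction": inter.p_value,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        fdr = fdr_correct(out["p_interaction"].to_numpy(), q=q)
        out["significant"] = fdr.significant
        out["p_fdr"] = fdr.p_fdr
    return out
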