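"""Sliding-window spectral analysis and the odorant-evoked Δ power statistic.

The central quantity is **Δ power**: the mean decibel band power of the LFP
over the first 2 s of odorant delivery minus the mean decibel band power in
a baseline window 2.1 to 0.6 s before odorant onset.  Power is estimated
with a sliding 1 s Hann-tapered short-time spectrum (1 Hz resolution) and
averaged on the dB scale.  An amplitude doubling of a band component during
the odorant therefore reads out as ~+6.02 dB in that band.

Conventions (stated because they affect numbers at the tenth-of-a-dB level):

* a time bin belongs to an interval iff its window *center* lies in the
  half-open interval ``[start, end)``;
* band membership is inclusive at both frequency edges;
* power is floored at ``db_floor`` (default −120 dB) before averaging so a
  silent channel yields a finite spectrum;
* signals sampled above ~1.2 kHz are decimated (anti-aliased) to 1 kHz
  before analysis — every analysis band lies below 100 Hz.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io import SessionBundle

__all__ = [
    "Band",
    "DEFAULT_BANDS",
    "Spectrogram",
    "bandpass",
    "spectrogram",
    "delta_power",
    "delta_power_spectrum",
    "delta_power_table",
    "delta_power_spectrum_table",
]


@dataclass(frozen=True)
class Band:
    name: str
    f_lo: float
    f_hi: float

    def validate(self, fs: float) -> None:
        if not (0 < self.f_lo < self.f_hi):
            raise ValueError(f"band {self.name}: need 0 < f_lo < f_hi")
        if self.f_hi >= fs / 2:
            raise ValueError(
                f"band {self.name}: f_hi {self.f_hi} at/above Nyquist {fs / 2}"
            )


#: Oscillation bands: theta, beta, low gamma, high gamma.
DEFAULT_BANDS = (
    Band("theta", 6.0, 12.0),
    Band("beta", 15.0, 30.0),
    Band("low_gamma", 35.0, 55.0),
    Band("high_gamma", 65.0, 95.0),
)

BAND_BY_NAME = {b.name: b for b in DEFAULT_BANDS}

RESPONSE_WINDOW_S = (0.0, 2.0)
BASELINE_WINDOW_S = (-2.1, -0.6)
ANALYSIS_RATE_HZ = 1000.0
DB_FLOOR = -120.0


def as_band(band) -> Band:
    if isinstance(band, Band):
        return band
    if isinstance(band, str):
        return BAND_BY_NAME[band]
    name = f"{band[0]:g}-{band[1]:g}Hz"
    return Band(name, float(band[0]), float(band[1]))


def bandpass(x: np.ndarray, band, fs: float, order: int = 4) -> np.ndarray:
    """Zero-phase band-pass (forward-backward Butterworth).

    Zero phase matters: lick/theta phase relationships downstream must not
    be distorted by filter group delay.
    """
    band = as_band(band)
    band.validate(fs)
    sos = sps.butter(order, [band.f_lo, band.f_hi], btype="band", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=-1)


def decimate_to_analysis_rate(x: np.ndarray, fs: float) -> tuple[np.ndarray, float]:
    """Anti-aliased decimation to ~1 kHz when the input rate exceeds it."""
    x = np.asarray(x)
    if fs <= 1.2 * ANALYSIS_RATE_HZ:
        return x, fs
    factor = int(round(fs / ANALYSIS_RATE_HZ))
    while factor > 1:
        step = min(factor, 10)
        x = sps.decimate(x, step, axis=-1, zero_phase=True)
        fs /= step
        factor //= step
    return x, fs


@dataclass
class Spectrogram:
    """Short-time power in dB: ``power_db[i_time, j_freq]``.

    ``times`` are window centers on the same clock as the source record.
    """

    power_db: np.ndarray
    times: np.ndarray
    freqs: np.ndarray
    window_s: float
    step_s: float
    db_floor: float


def spectrogram(
    x: np.ndarray,
    fs: float,
    window_s: float = 1.0,
    step_s: float = 0.1,
    t0: float = 0.0,
    db_floor: float = DB_FLOOR,
) -> Spectrogram:
    """Sliding-window Hann-tapered power spectral density in dB.

    1 s window at 1 kHz gives 1 Hz frequency resolution; dB is
    ``10*log10(PSD)`` with the configured floor.
    """
    x = np.asarray(x, dtype=float)
    nperseg = int(round(window_s * fs))
    step = int(round(step_s * fs))
    if step < 1:
        raise ValueError("step_s too small for the sampling rate")
    if x.shape[-1] < nperseg:
        raise ValueError(
            f"signal ({x.shape[-1]} samples) shorter than window ({nperseg})"
        )
    freqs, times, psd = sps.spectrogram(
        x,
        fs=fs,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg - step,
        detrend=False,
        scaling="density",
        mode="psd",
    )
    floor_lin = 10.0 ** (db_floor / 10.0)
    power_db = 10.0 * np.log10(np.maximum(psd.T, floor_lin))
    return Spectrogram(
        power_db=power_db,
        times=times + t0,
        freqs=freqs,
        window_s=window_s,
        step_s=step_s,
        db_floor=db_floor,
    )


def _time_mask(spec: Spectrogram, start: float, end: float, what: str) -> np.ndarray:
    mask = (spec.times >= start) & (spec.times < end)
    if not mask.any():
        raise ValueError(
            f"spectrogram does not cover the {what} interval [{start:.3f}, {end:.3f}) s"
        )
    return mask


def _freq_mask(spec: Spectrogram, f_lo: float, f_hi: float) -> np.ndarray:
    mask = (spec.freqs >= f_lo) & (spec.freqs <= f_hi)
    if not mask.any():
        raise ValueError(f"no frequency bins in [{f_lo}, {f_hi}] Hz")
    return mask


def delta_power(
    spec: Spectrogram,
    odorant_onset_s: float,
    band,
    response_window_s: tuple = RESPONSE_WINDOW_S,
    baseline_window_s: tuple = BASELINE_WINDOW_S,
    db_average: bool = True,
) -> float:
    """Odorant-evoked change in band power, in dB.

    Mean dB power over bins whose window centers fall in
    ``onset + response_window`` and whose frequencies lie in ``band``,
    minus the same mean over ``onset + baseline_window``.  ``db_average``
    switches to linear-power averaging (converted to dB at the end) if
    False.
    """
    band = as_band(band)
    r0, r1 = (odorant_onset_s + w for w in response_window_s)
    b0, b1 = (odorant_onset_s + w for w in baseline_window_s)
    tm_r = _time_mask(spec, r0, r1, "response")
    tm_b = _time_mask(spec, b0, b1, "baseline")
    fm = _freq_mask(spec, band.f_lo, band.f_hi)
    if db_average:
        resp = spec.power_db[np.ix_(tm_r, fm)].mean()
        base = spec.power_db[np.ix_(tm_b, fm)].mean()
    else:
        lin = 10.0 ** (spec.power_db / 10.0)
        resp = 10.0 * np.log10(lin[np.ix_(tm_r, fm)].mean())
        base = 10.0 * np.log10(lin[np.ix_(tm_b, fm)].mean())
    return float(resp - base)


def delta_power_spectrum(
    spec: Spectrogram,
    odorant_onset_s: float,
    freq_range: tuple = (4.0, 100.0),
    response_window_s: tuple = RESPONSE_WINDOW_S,
    baseline_window_s: tuple = BASELINE_WINDOW_S,
) -> pd.DataFrame:
    """Per-frequency Δ power (dB) over ``freq_range`` — the Δ power spectrum."""
    r0, r1 = (odorant_onset_s + w for w in response_window_s)
    b0, b1 = (odorant_onset_s + w for w in baseline_window_s)
    tm_r = _time_mask(spec, r0, r1, "response")
    tm_b = _time_mask(spec, b0, b1, "baseline")
    fm = _freq_mask(spec, *freq_range)
    delta = spec.power_db[tm_r][:, fm].mean(axis=0) - spec.power_db[tm_b][:, fm].mean(
        axis=0
    )
    return pd.DataFrame({"freq_hz": spec.freqs[fm], "delta_db": delta})


def _session_spectrograms(
    bundle: SessionBundle, window_s: float, step_s: float, chunk: int = 16
):
    """Per-electrode spectrograms covering every trial's analysis window.

    Electrodes are processed in vectorized batches, and the signal is
    cropped to the span of the trials first.  The crop offset is snapped to
    the step grid so bin centers (hence every Δ power value) are identical
    to an uncropped computation.
    """
    fs = bundle.lfp.sampling_rate_hz
    onsets = [tr.odorant_onset_s for tr in bundle.trials]
    sig = bundle.lfp.signal
    t0 = bundle.lfp.t0
    if onsets:
        t_lo = min(onsets) + BASELINE_WINDOW_S[0] - window_s
        t_hi = max(onsets) + RESPONSE_WINDOW_S[1] + window_s
        step_samp = max(int(round(step_s * fs)), 1)
        i0 = max(0, int((t_lo - t0) * fs) // step_samp * step_samp)
        i1 = min(sig.shape[1], int(np.ceil((t_hi - t0) * fs)))
        sig = sig[:, i0:i1]
        t0 = t0 + i0 / fs
    for e0 in range(0, sig.shape[0], chunk):
        e1 = min(e0 + chunk, sig.shape[0])
        x, fs_a = decimate_to_analysis_rate(sig[e0:e1], fs)
        nperseg = int(round(window_s * fs_a))
        step = int(round(step_s * fs_a))
        freqs, times, psd = sps.spectrogram(
            x,
            fs=fs_a,
            window="hann",
            nperseg=nperseg,
            noverlap=nperseg - step,
            detrend=False,
            scaling="density",
            mode="psd",
        )
        floor_lin = 10.0 ** (DB_FLOOR / 10.0)
        power_db = 10.0 * np.log10(np.maximum(psd, floor_lin))
        for j, e in enumerate(range(e0, e1)):
            yield e, Spectrogram(
                power_db=power_db[j].T,
                times=times + t0,
                freqs=freqs,
                window_s=window_s,
                step_s=step_s,
                db_floor=DB_FLOOR,
            )


def delta_power_table(
    bundle: SessionBundle,
    bands=DEFAULT_BANDS,
    window_s: float = 1.0,
    step_s: float = 0.1,
    db_average: bool = True,
) -> pd.DataFrame:
    """Δ power per (trial, electrode, band) for a whole session.

    Long-format frame with columns ``trial_index, electrode, band, delta_db,
    valence, outcome`` — directly consumable by the ROC machinery.
    """
    bands = [as_band(b) for b in bands]
    masks = None
    rows = []
    for e, spec in _session_spectrograms(bundle, window_s, step_s):
        if masks is None:
            # bin masks depend only on the (shared) time/freq grids
            masks = []
            fmasks = [
                (spec.freqs >= b.f_lo) & (spec.freqs <= b.f_hi) for b in bands
            ]
            for tr in bundle.trials:
                on = tr.odorant_onset_s
                tm_r = (spec.times >= on + RESPONSE_WINDOW_S[0]) & (
                    spec.times < on + RESPONSE_WINDOW_S[1]
                )
                tm_b = (spec.times >= on + BASELINE_WINDOW_S[0]) & (
                    spec.times < on + BASELINE_WINDOW_S[1]
                )
                if not (tm_r.any() and tm_b.any()):
                    warnings.warn(
                        f"trial {tr.trial_index}: insufficient spectrogram coverage; "
                        "flagged excluded"
                    )
                    masks.append(None)
                else:
                    masks.append((tm_r, tm_b))
        P = spec.power_db if db_average else 10.0 ** (spec.power_db / 10.0)
        for tr, m in zip(bundle.trials, masks):
            if m is None:
                deltas = [np.nan] * len(bands)
            else:
                tm_r, tm_b = m
                prof_r = P[tm_r].mean(axis=0)
                prof_b = P[tm_b].mean(axis=0)
                if db_average:
                    deltas = [
                        float(prof_r[fm].mean() - prof_b[fm].mean()) for fm in fmasks
                    ]
                else:
                    deltas = [
                        float(
                            10.0 * np.log10(prof_r[fm].mean())
                            - 10.0 * np.log10(prof_b[fm].mean())
                        )
                        for fm in fmasks
                    ]
            for band, d in zip(bands, deltas):
                rows.append(
                    {
                        "trial_index": tr.trial_index,
                        "electrode": e,
                        "band": band.name,
                        "delta_db": d,
                        "valence": tr.odorant_valence.value,
                        "outcome": None if tr.outcome is None else tr.outcome.value,
                    }
                )
    return pd.DataFrame(rows)


def delta_power_spectrum_table(
    bundle: SessionBundle,
    freq_range: tuple = (4.0, 100.0),
    window_s: float = 1.0,
    step_s: float = 0.1,
) -> pd.DataFrame:
    """Per-frequency Δ power averaged over trials, per electrode and valence."""
    frames = []
    for e, spec in _session_spectrograms(bundle, window_s, step_s):
        for tr in bundle.trials:
            df = delta_power_spectrum(spec, tr.odorant_onset_s, freq_range)
            df["electrode"] = e
            df["trial_index"] = tr.trial_index
            df["valence"] = tr.odorant_valence.value
            frames.append(df)
    long = pd.concat(frames, ignore_index=True)
    return (
        long.groupby(["electrode", "valence", "freq_hz"], as_index=False)["delta_db"]
        .mean()
    )
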