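"""Trial outcome classification, percent correct, learning criterion, epochs.

A trial counts as a *response* iff each of the four consecutive 0.5 s
intervals starting at odorant onset contains at least one lick (the task's
reward criterion).  Outcomes partition trials: Hit = S+ with response,
Miss = S+ without, FA = S− with response, CR = S− without.

Percent correct is computed over a trailing 20-trial window (the task is
scored in 20-trial blocks; the trailing window matches per-trial learning
curves, and a block-wise summary is also exposed).  A mouse has *reached
criterion* once at least two sessions end with >= 80% correct over their
final 40 trials.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Outcome, SessionBundle, TrialEvent, Valence

__all__ = [
    "classify_trial",
    "outcome_table",
    "sliding_percent_correct",
    "blockwise_percent_correct",
    "reached_criterion",
    "EpochSelection",
    "select_epoch",
]

RESPONSE_INTERVALS = 4
RESPONSE_INTERVAL_S = 0.5
CRITERION_PERCENT = 80.0
CRITERION_TRIALS = 40


def classify_trial(trial: TrialEvent) -> Outcome:
    """Outcome from lick times and valence via the four-interval criterion."""
    if trial.odorant_onset_s is None or not np.isfinite(trial.odorant_onset_s):
        raise ValueError(f"trial {trial.trial_index}: missing odorant onset")
    licks = np.asarray(trial.lick_times_s, dtype=float)
    response = True
    for k in range(RESPONSE_INTERVALS):
        w0 = trial.odorant_onset_s + k * RESPONSE_INTERVAL_S
        w1 = w0 + RESPONSE_INTERVAL_S
        if not np.any((licks >= w0) & (licks < w1)):
            response = False
            break
    if trial.odorant_valence is Valence.Splus:
        return Outcome.Hit if response else Outcome.Miss
    return Outcome.FA if response else Outcome.CR


def outcome_table(bundle: SessionBundle, reclassify: bool = False) -> pd.DataFrame:
    """Per-trial outcome table; recomputes outcomes from licks if asked or absent."""
    rows = []
    for tr in bundle.trials:
        outcome = tr.outcome
        if reclassify or outcome is None:
            outcome = classify_trial(tr)
        rows.append(
            {
                "trial_index": tr.trial_index,
                "valence": tr.odorant_valence.value,
                "outcome": outcome.value,
                "response": outcome in (Outcome.Hit, Outcome.FA),
                "correct": outcome in (Outcome.Hit, Outcome.CR),
            }
        )
    return pd.DataFrame(rows)


def sliding_percent_correct(outcomes: pd.DataFrame, window: int = 20) -> pd.DataFrame:
    """Trailing-window percent correct: 100 x (#Hit + #CR) / window."""
    if window < 1:
        raise ValueError("window must be >= 1")
    if len(outcomes) < window:
        raise ValueError(f"need at least {window} trials, have {len(outcomes)}")
    correct = outcomes["correct"].to_numpy(dtype=float)
    pc = 100.0 * pd.Series(correct).rolling(window).mean().to_numpy()
    df = pd.DataFrame(
        {"trial_index": outcomes["trial_index"].to_numpy(), "percent_correct": pc}
    )
    return df.iloc[window - 1 :].reset_index(drop=True)


def blockwise_percent_correct(outcomes: pd.DataFrame, block: int = 20) -> pd.DataFrame:
    """Percent correct per disjoint block (the task's native scoring)."""
    correct = outcomes["correct"].to_numpy(dtype=float)
    n_blocks = len(correct) // block
    rows = [
        {
            "block": b,
            "percent_correct": 100.0 * correct[b * block : (b + 1) * block].mean(),
        }
        for b in range(n_blocks)
    ]
    return pd.DataFrame(rows)


def reached_criterion(session_outcomes: list) -> bool:
    """True iff >= 2 sessions score >= 80% correct over their final 40 trials."""
    n_good = 0
    for i, outcomes in enumerate(session_outcomes):
        if len(outcomes) < CRITERION_TRIALS:
            warnings.warn(f"session {i}: fewer than {CRITERION_TRIALS} trials, skipped")
            continue
        tail = outcomes["correct"].to_numpy()[-CRITERION_TRIALS:]
        if 100.0 * tail.mean() >= CRITERION_PERCENT:
            n_good += 1
    return n_good >= 2


@dataclass
class EpochSelection:
    label: str
    session_pos: int  # position in the supplied session list
    trial_positions: np.ndarray  # contiguous positions within that session
    n_trials: int


def _session_percent_last40(bundle: SessionBundle) -> float:
    tab = outcome_table(bundle)
    tail = tab["correct"].to_numpy()[-CRITERION_TRIALS:]
    return 100.0 * tail.mean()


def select_epoch(sessions: list, label: str, n_trials: int) -> EpochSelection:
    """Pick the analysis epoch for a figure-level contrast.

    naive       first ``n_trials`` of the first session;
    proficient  last ``n_trials`` of the last session meeting the 80%
                criterion (falls back to the last session if none does);
    pre_laser   last ``n_trials`` of the last laser-off session;
    laser       first ``n_trials`` of the first laser-on session.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if not sessions:
        raise ValueError("no sessions supplied")

    if label == "naive":
        pos, take = 0, "first"
    elif label == "proficient":
        pos = None
        for i in range(len(sessions) - 1, -1, -1):
            if (
                len(sessions[i].trials) >= CRITERION_TRIALS
                and _session_percent_last40(sessions[i]) >= CRITERION_PERCENT
            ):
                pos = i
                break
        if pos is None:
            pos = len(sessions) - 1
        take = "last"
    elif label == "pre_laser":
        candidates = [i for i, s in enumerate(sessions) if not s.meta.laser_enabled]
        if not candidates:
            raise ValueError("no laser-off session available for pre_laser epoch")
        pos, take = candidates[-1], "last"
    elif label == "laser":
        candidates = [i for i, s in enumerate(sessions) if s.meta.laser_enabled]
        if not candidates:
            raise ValueError("no laser-on session available for laser epoch")
        pos, take = candidates[0], "first"
    else:
        raise ValueError(f"unknown epoch label {label!r}")

    n_avail = len(sessions[pos].trials)
    if n_avail < n_trials:
        raise ValueError(
            f"epoch {label}: session has {n_avail} trials, {n_trials} requested"
        )
    if take == "first":
        idx = np.arange(n_trials)
    else:
        idx = np.arange(n_avail - n_trials, n_avail)
    return EpochSelection(
        label=label, session_pos=pos, trial_positions=idx, n_trials=n_trials
    )
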