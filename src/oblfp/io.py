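"""Session data model and on-disk format.

A *session* is one go/no-go behavioral run: continuous multi-electrode LFP,
a per-trial event table (port entry, odorant onset and valence, licks,
optional laser interval, outcome), and metadata (mouse, genotype, odorant
pair, sampling rate).  All event times are in seconds on the LFP clock
(``t0`` = time of the first sample); the continuous signal is the single
source of truth and no per-trial clipping is stored.

On disk a session is a directory of four plain files:

``meta.json``
    every :class:`SessionMeta` field.
``events.csv``
    one row per trial: ``trial_index, port_entry_s, odorant_onset_s,
    odorant_valence, odorant_duration_s, laser_on_s, laser_off_s, outcome``.
``licks.csv``
    ``trial_index, time_s`` — one row per lick.
``lfp.bin`` + ``lfp.json``
    little-endian float32, electrode-major (C order, shape
    ``[n_electrodes, n_samples]``), microvolts; the JSON sidecar records
    shape, dtype, ``t0`` and sampling rate so the format is self-describing.

Round-trips are lossless (bit-exact for the binary payload).
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Valence",
    "Genotype",
    "Outcome",
    "SessionMeta",
    "LfpRecord",
    "TrialEvent",
    "SessionBundle",
    "SessionValidationError",
    "write_session",
    "read_session",
]

LFP_DTYPE = "<f4"


class SessionValidationError(ValueError):
    """Raised when a bundle or on-disk session violates the schema."""

    def __init__(self, field_name: str, message: str):
        self.field_name = field_name
        super().__init__(f"{field_name}: {message}")


class Valence(str, enum.Enum):
    Splus = "Splus"
    Sminus = "Sminus"


class Genotype(str, enum.Enum):
    """``control`` = driver line only; ``opsin`` = driver line x halorhodopsin."""

    control = "control"
    opsin = "opsin"


class Outcome(str, enum.Enum):
    Hit = "Hit"
    Miss = "Miss"
    CR = "CR"
    FA = "FA"


#: Convention: a session's two odorants are labelled "A" and "B";
#: ``SessionMeta.reward_mapping`` names the one delivered as S+.
ODORANT_LABELS = ("A", "B")


@dataclass
class SessionMeta:
    mouse_id: str
    genotype: Genotype = Genotype.control
    odorant_pair: str = "APEB"
    session_index: int = 1
    sampling_rate_hz: float = 1000.0
    n_electrodes: int = 16
    laser_enabled: bool = False
    reward_mapping: str = "A"

    def validate(self) -> None:
        if not self.mouse_id:
            raise SessionValidationError("mouse_id", "must be non-empty")
        self.genotype = Genotype(self.genotype)
        if self.session_index < 1:
            raise SessionValidationError("session_index", "must be >= 1")
        # all analysis bands live below 100 Hz; demand a usable Nyquist
        if self.sampling_rate_hz < 200.0:
            raise SessionValidationError(
                "sampling_rate_hz", f"must be >= 200 Hz, got {self.sampling_rate_hz}"
            )
        if self.n_electrodes < 1:
            raise SessionValidationError("n_electrodes", "must be >= 1")
        if self.reward_mapping not in ODORANT_LABELS:
            raise SessionValidationError(
                "reward_mapping", f"must be one of {ODORANT_LABELS}"
            )

    def to_dict(self) -> dict:
        return {
            "mouse_id": self.mouse_id,
            "genotype": self.genotype.value,
            "odorant_pair": self.odorant_pair,
            "session_index": self.session_index,
            "sampling_rate_hz": self.sampling_rate_hz,
            "n_electrodes": self.n_electrodes,
            "laser_enabled": self.laser_enabled,
            "reward_mapping": self.reward_mapping,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SessionMeta":
        return cls(
            mouse_id=d["mouse_id"],
            genotype=Genotype(d["genotype"]),
            odorant_pair=d["odorant_pair"],
            session_index=int(d["session_index"]),
            sampling_rate_hz=float(d["sampling_rate_hz"]),
            n_electrodes=int(d["n_electrodes"]),
            laser_enabled=bool(d["laser_enabled"]),
            reward_mapping=d["reward_mapping"],
        )


@dataclass
class LfpRecord:
    """Continuous multi-electrode LFP in microvolts, shape [n_electrodes, n_samples]."""

    signal: np.ndarray
    sampling_rate_hz: float
    t0: float = 0.0

    @property
    def n_electrodes(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def t_end(self) -> float:
        return self.t0 + (self.n_samples - 1) / self.sampling_rate_hz

    def validate(self) -> None:
        if self.signal.ndim != 2:
            raise SessionValidationError("lfp.signal", "must be 2-D [electrodes, samples]")
        if not np.all(np.isfinite(self.signal)):
            raise SessionValidationError("lfp.signal", "contains non-finite values")
        if self.sampling_rate_hz <= 0:
            raise SessionValidationError("lfp.sampling_rate_hz", "must be positive")


@dataclass
class TrialEvent:
    trial_index: int
    port_entry_s: float
    odorant_onset_s: float
    odorant_valence: Valence
    odorant_duration_s: float = 2.5
    lick_times_s: list = field(default_factory=list)
    laser_on_s: float | None = None
    laser_off_s: float | None = None
    outcome: Outcome | None = None

    def odorant_label(self, reward_mapping: str) -> str:
        """Odorant identity ("A"/"B") from valence plus the session's reward mapping."""
        a, b = ODORANT_LABELS
        if self.odorant_valence is Valence.Splus:
            return reward_mapping
        return b if reward_mapping == a else a

    def validate(self) -> None:
        self.odorant_valence = Valence(self.odorant_valence)
        if self.outcome is not None:
            self.outcome = Outcome(self.outcome)
        where = f"trial {self.trial_index}"
        if not math.isfinite(self.port_entry_s) or not math.isfinite(self.odorant_onset_s):
            raise SessionValidationError(where, "non-finite event time")
        if self.odorant_onset_s <= self.port_entry_s:
            raise SessionValidationError(
                where, "odorant_onset_s must follow port_entry_s"
            )
        if self.odorant_duration_s <= 0:
            raise SessionValidationError(where, "odorant_duration_s must be positive")
        licks = np.asarray(self.lick_times_s, dtype=float)
        if licks.size:
            if np.any(np.diff(licks) <= 0):
                raise SessionValidationError(
                    where, "lick times must be strictly increasing"
                )
            if licks[0] < self.port_entry_s:
                raise SessionValidationError(
                    where, "lick before port entry"
                )
        if (self.laser_on_s is None) != (self.laser_off_s is None):
            raise SessionValidationError(where, "laser_on_s/laser_off_s must come together")
        if self.laser_on_s is not None and self.laser_off_s <= self.laser_on_s:
            raise SessionValidationError(where, "laser_off_s must follow laser_on_s")


#: Time the spectral analysis needs on each side of the odorant onset:
#: baseline window starts 2.1 s before onset, response window ends 2 s after,
#: and the sliding 1 s window adds half a window on each side.
TRIAL_PAD_BEFORE_S = 2.1 + 0.5
TRIAL_PAD_AFTER_S = 2.5 + 0.5


@dataclass
class SessionBundle:
    meta: SessionMeta
    lfp: LfpRecord
    trials: list

    def validate(self) -> None:
        self.meta.validate()
        self.lfp.validate()
        if self.lfp.n_electrodes != self.meta.n_electrodes:
            raise SessionValidationError(
                "n_electrodes",
                f"meta says {self.meta.n_electrodes}, lfp has {self.lfp.n_electrodes}",
            )
        if self.lfp.sampling_rate_hz != self.meta.sampling_rate_hz:
            raise SessionValidationError(
                "sampling_rate_hz", "meta and lfp sidecar disagree"
            )
        onsets = []
        for tr in self.trials:
            tr.validate()
            onsets.append(tr.odorant_onset_s)
            if tr.odorant_onset_s - TRIAL_PAD_BEFORE_S < self.lfp.t0 or (
                tr.odorant_onset_s + TRIAL_PAD_AFTER_S > self.lfp.t_end
            ):
                raise SessionValidationError(
                    f"trial {tr.trial_index}",
                    "analysis window extends beyond the LFP record",
                )
        if np.any(np.diff(onsets) <= 0):
            raise SessionValidationError("trials", "must be sorted by odorant onset")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def subset(self, trial_indices) -> "SessionBundle":
        """Bundle restricted to the given trial positions (LFP untouched)."""
        trials = [self.trials[i] for i in trial_indices]
        return replace(self, trials=trials)


_EVENT_COLUMNS = [
    "trial_index",
    "port_entry_s",
    "odorant_onset_s",
    "odorant_valence",
    "odorant_duration_s",
    "laser_on_s",
    "laser_off_s",
    "outcome",
]


def write_session(bundle: SessionBundle, path) -> Path:
    """Write a validated bundle to ``path`` (created if needed); returns the path."""
    bundle.validate()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    (path / "meta.json").write_text(
        json.dumps(bundle.meta.to_dict(), indent=2, sort_keys=True) + "\n"
    )

    rows = []
    lick_rows = []
    for tr in bundle.trials:
        rows.append(
            {
                "trial_index": tr.trial_index,
                "port_entry_s": tr.port_entry_s,
                "odorant_onset_s": tr.odorant_onset_s,
                "odorant_valence": tr.odorant_valence.value,
                "odorant_duration_s": tr.odorant_duration_s,
                "laser_on_s": "" if tr.laser_on_s is None else tr.laser_on_s,
                "laser_off_s": "" if tr.laser_off_s is None else tr.laser_off_s,
                "outcome": "" if tr.outcome is None else tr.outcome.value,
            }
        )
        for t in tr.lick_times_s:
            lick_rows.append({"trial_index": tr.trial_index, "time_s": t})
    pd.DataFrame(rows, columns=_EVENT_COLUMNS).to_csv(
        path / "events.csv", index=False, float_format="%.9g"
    )
    pd.DataFrame(lick_rows, columns=["trial_index", "time_s"]).to_csv(
        path / "licks.csv", index=False, float_format="%.9g"
    )

    sig = np.ascontiguousarray(bundle.lfp.signal, dtype=LFP_DTYPE)
    sig.tofile(path / "lfp.bin")
    sidecar = {
        "shape": list(sig.shape),
        "dtype": LFP_DTYPE,
        "t0": bundle.lfp.t0,
        "sampling_rate_hz": bundle.lfp.sampling_rate_hz,
        "order": "electrode-major",
        "units": "microvolts",
    }
    (path / "lfp.json").write_text(json.dumps(sidecar, indent=2, sort_keys=True) + "\n")
    return path


def _require(path: Path) -> Path:
    if not path.exists():
        raise SessionValidationError(str(path), "missing file")
    return path


def read_session(path) -> SessionBundle:
    """Read and validate a session directory written by :func:`write_session`."""
    path = Path(path)
    meta = SessionMeta.from_dict(json.loads(_require(path / "meta.json").read_text()))

    sidecar = json.loads(_require(path / "lfp.json").read_text())
    shape = tuple(int(s) for s in sidecar["shape"])
    dtype = np.dtype(sidecar["dtype"])
    raw = np.fromfile(_require(path / "lfp.bin"), dtype=dtype)
    expected = shape[0] * shape[1]
    if raw.size != expected:
        raise SessionValidationError(
            "lfp.bin",
            f"sidecar shape {shape} implies {expected} samples, file has {raw.size}",
        )
    lfp = LfpRecord(
        signal=raw.reshape(shape),
        sampling_rate_hz=float(sidecar["sampling_rate_hz"]),
        t0=float(sidecar["t0"]),
    )

    events = pd.read_csv(_require(path / "events.csv"))
    missing = set(_EVENT_COLUMNS) - set(events.columns)
    if missing:
        raise SessionValidationError("events.csv", f"missing columns {sorted(missing)}")
    licks_df = pd.read_csv(_require(path / "licks.csv"))
    licks_by_trial: dict[int, list] = {}
    for _, row in licks_df.iterrows():
        licks_by_trial.setdefault(int(row["trial_index"]), []).append(float(row["time_s"]))

    trials = []
    for pos, row in events.iterrows():
        tok = str(row["odorant_valence"])
        try:
            valence = Valence(tok)
        except ValueError:
            raise SessionValidationError(
                "events.csv", f"row {pos}: unknown valence token {tok!r}"
            ) from None
        outcome = None
        if not (pd.isna(row["outcome"]) or str(row["outcome"]) == ""):
            try:
                outcome = Outcome(str(row["outcome"]))
            except ValueError:
                raise SessionValidationError(
                    "events.csv", f"row {pos}: unknown outcome token {row['outcome']!r}"
                ) from None
        laser_on = None if pd.isna(row["laser_on_s"]) else float(row["laser_on_s"])
        laser_off = None if pd.isna(row["laser_off_s"]) else float(row["laser_off_s"])
        trials.append(
            TrialEvent(
                trial_index=int(row["trial_index"]),
                port_entry_s=float(row["port_entry_s"]),
                odorant_onset_s=float(row["odorant_onset_s"]),
                odorant_valence=valence,
                odorant_duration_s=float(row["odorant_duration_s"]),
                lick_times_s=licks_by_trial.get(int(row["trial_index"]), []),
                laser_on_s=laser_on,
                laser_off_s=laser_off,
                outcome=outcome,
            )
        )

    bundle = SessionBundle(meta=meta, lfp=lfp, trials=trials)
    bundle.validate()
    return bundle
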