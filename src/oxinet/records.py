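"""Core data containers: SpO2 traces and scored event annotations.

The oximetry trace is the only physiological signal consumed anywhere in
this package.  Invalid samples (oximeter dropouts, motion artifacts) are
carried as an explicit boolean mask rather than a magic numeric code so
that downstream code is forced to handle them deliberately; the ``samples``
array holds NaN at invalid positions as a secondary guard.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

EVENT_KINDS = ("apnea", "hypopnea", "desaturation")

#: kinds that count toward the apnea-hypopnea index
RESPIRATORY_KINDS = ("apnea", "hypopnea")


@dataclass
class SpO2Record:
    """A uniformly sampled blood oxygen saturation trace.

    Parameters
    ----------
    samples : ndarray of float
        Saturation in percent.  NaN at invalid positions.
    fs : float
        Sampling frequency in Hz (nominally 4 for ambulatory oximeters).
    valid : ndarray of bool, optional
        Per-sample validity flag.  Defaults to ``~isnan(samples)``.
    """

    samples: np.ndarray
    fs: float
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.fs <= 0:
            raise ValueError(f"sampling frequency must be positive, got {self.fs}")
        if self.valid is None:
            self.valid = ~np.isnan(self.samples)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.samples.shape:
                raise ValueError("valid mask shape must match samples")
        vals = self.samples[self.valid]
        if vals.size and (np.nanmin(vals) < 0 or np.nanmax(vals) > 100):
            raise ValueError("valid SpO2 samples must lie in [0, 100] %")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def to_csv(self, path: str | Path) -> None:
        """Write ``time_s,spo2`` CSV; invalid samples emitted as empty cells."""
        df = pd.DataFrame({"time_s": self.times, "spo2": self.samples})
        df.loc[~self.valid, "spo2"] = np.nan
        df.to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpO2Record":
        df = pd.read_csv(path, float_precision="round_trip")
        if not {"time_s", "spo2"}.issubset(df.columns):
            raise ValueError(f"{path}: expected columns time_s,spo2")
        t = df["time_s"].to_numpy(dtype=float)
        if len(t) < 2:
            raise ValueError(f"{path}: need at least two samples to infer fs")
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError(f"{path}: non-uniform sampling")
        return cls(samples=df["spo2"].to_numpy(dtype=float), fs=1.0 / dt[0])

    @classmethod
    def from_edf(cls, path: str | Path, channel: str = "SpO2") -> "SpO2Record":
        """Read a single saturation channel from an EDF file (requires mne)."""
        import mne  # local import: EDF support is optional

        raw = mne.io.read_raw_edf(str(path), include=[channel], preload=True,
                                  verbose="error")
        data = raw.get_data(picks=[channel])[0]
        return cls(samples=np.asarray(data, dtype=float), fs=float(raw.info["sfreq"]))


@dataclass(frozen=True)
class Event:
    """One scored event: apnea, hypopnea, or oxygen desaturation."""

    kind: str
    onset_s: float
    duration_s: float

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.onset_s < 0:
            raise ValueError("event onset must be >= 0")
        if self.duration_s <= 0:
            raise ValueError("event duration must be > 0")


@dataclass
class EventAnnotation:
    """Scored events for one recording, sorted by onset.

    Reference indices follow the ambulatory (HSAT) convention: the
    denominator is total recording time, since no EEG is available to
    restrict to sleep time.
    """

    events: list[Event] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: e.onset_s)

    def __len__(self) -> int:
        return len(self.events)

    def onsets(self, kinds: Sequence[str]) -> np.ndarray:
        return np.array([e.onset_s for e in self.events if e.kind in kinds],
                        dtype=float)

    def count(self, kinds: Iterable[str]) -> int:
        kinds = set(kinds)
        return sum(1 for e in self.events if e.kind in kinds)

    def reference_ahi(self, duration_s: float) -> float:
        """Apneas + hypopneas per hour of recording."""
        from .scoring import compute_index

        return compute_index(self.count(RESPIRATORY_KINDS), duration_s)

    def reference_odi(self, duration_s: float) -> float:
        """Desaturation events per hour of recording."""
        from .scoring import compute_index

        return compute_index(self.count(["desaturation"]), duration_s)

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "kind": [e.kind for e in self.events],
                "onset_s": [e.onset_s for e in self.events],
                "duration_s": [e.duration_s for e in self.events],
            }
        )
        # full repr precision so the round trip is exact
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "EventAnnotation":
        df = pd.read_csv(path, float_precision="round_trip")
        if df.empty:
            return cls([])
        return cls(
            [
                Event(str(k), float(o), float(d))
                for k, o, d in zip(df["kind"], df["onset_s"], df["duration_s"])
            ]
        )
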