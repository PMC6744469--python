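"""Desaturation detection, index computation, and OSA severity classes.

The detector follows the AASM-2007 convention that an oxygen desaturation
is a drop of at least 4 percentage points of SpO2 below the local
baseline.  Since manual scorers' baseline rules are not standardised, the
detector here uses an explicit, configurable definition:

* the baseline at time t is the maximum valid sample over the preceding
  120 s (the pre-event plateau);
* a candidate opens when the signal falls >= ``min_drop`` points below
  that baseline; its onset is backtracked to the last preceding sample
  still within ``onset_margin`` (0.5 points, i.e. at the baseline level
  on an integer-quantized trace) of the baseline — the moment the signal
  left the baseline;
* the candidate closes when the signal recovers to within 1 point of the
  (frozen) baseline, or after a 300 s timeout, or at an invalid sample;
* overlapping candidates are merged.

These window/recovery parameters are calibration knobs, not claims about
any particular scorer.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from .records import SpO2Record

BASELINE_WINDOW_S = 120.0
RECOVERY_MARGIN = 1.0
ONSET_MARGIN = 0.5
EVENT_TIMEOUT_S = 300.0


class SeverityCategory(IntEnum):
    """OSA severity, ordered; thresholds at AHI 5, 15 and 30 events/hour."""

    NO_OSA = 0
    MILD = 1
    MODERATE = 2
    SEVERE = 3

    @property
    def label(self) -> str:
        return self.name.lower()


SEVERITY_LABELS = tuple(c.label for c in SeverityCategory)


@dataclass(frozen=True)
class DesaturationEvent:
    """One detected desaturation: onset, nadir, depth below baseline."""

    onset_s: float
    nadir_s: float
    depth: float
    duration_s: float

    def __post_init__(self) -> None:
        if not self.onset_s < self.nadir_s:
            raise ValueError("nadir must come after onset")
        if self.depth < 0:
            raise ValueError("depth must be non-negative")


def compute_index(events: int, duration_s: float) -> float:
    """Events per hour: 3600 * count / duration."""
    if duration_s <= 0:
        raise ValueError(f"duration must be positive, got {duration_s}")
    if events < 0:
        raise ValueError("event count must be non-negative")
    return 3600.0 * events / duration_s


def classify_severity(index: float) -> SeverityCategory:
    """Map an AHI (or ODI) value to the four-class OSA severity scale.

    Intervals are left-closed: [0, 5) no OSA, [5, 15) mild, [15, 30)
    moderate, [30, inf) severe — boundary values belong to the higher
    class.
    """
    if index < 0:
        raise ValueError(f"index must be non-negative, got {index}")
    if index < 5:
        return SeverityCategory.NO_OSA
    if index < 15:
        return SeverityCategory.MILD
    if index < 30:
        return SeverityCategory.MODERATE
    return SeverityCategory.SEVERE


def detect_desaturations(record: SpO2Record, min_drop: float = 4.0,
                         baseline_window_s: float = BASELINE_WINDOW_S,
                         recovery_margin: float = RECOVERY_MARGIN,
                         onset_margin: float = ONSET_MARGIN,
                         timeout_s: float = EVENT_TIMEOUT_S,
                         ) -> list[DesaturationEvent]:
    """Detect >= ``min_drop``-point desaturations against a sliding baseline.

    Parameters
    ----------
    record : SpO2Record
        Saturation trace at any sampling rate; invalid samples terminate
        any open candidate event.
    min_drop : float
        Threshold in percentage points (4 by default; 3 reproduces the
        more recent 3%-desaturation convention).

    Returns
    -------
    list of DesaturationEvent, sorted by onset.
    """
    if min_drop <= 0:
        raise ValueError("min_drop must be positive")
    if not record.valid.any():
        raise ValueError("record contains no valid samples")
    from scipy.ndimage import maximum_filter1d

    s = record.samples
    valid = record.valid
    fs = record.fs
    n = s.size
    win = max(int(round(baseline_window_s * fs)), 1)
    timeout_n = int(round(timeout_s * fs))

    # prev_max[i] = max valid sample over the `win` samples preceding i
    s_masked = np.where(valid, s, -np.inf)
    trail = maximum_filter1d(s_masked, size=win, mode="constant",
                             cval=-np.inf, origin=(win - 1) // 2)
    prev_max = np.empty(n)
    prev_max[0] = -np.inf
    prev_max[1:] = trail[:-1]

    with np.errstate(invalid="ignore"):
        candidates = np.flatnonzero(
            valid & np.isfinite(prev_max) & (s <= prev_max - min_drop)
        )

    events: list[DesaturationEvent] = []
    consumed_until = 0
    for i in candidates:
        if i < consumed_until:
            continue
        baseline = prev_max[i]
        # forward scan: event runs while the signal stays > 1 point below
        # the frozen baseline, up to timeout or dropout
        stop = min(n, i + timeout_n + 1)
        seg, segv = s[i:stop], valid[i:stop]
        with np.errstate(invalid="ignore"):
            closing = (~segv) | (seg >= baseline - recovery_margin)
        rel = np.flatnonzero(closing)
        end = i + (int(rel[0]) - 1 if rel.size else stop - i - 1)
        # backtrack the onset to the start of the decline
        lo = max(0, i - win)
        back, backv = s[lo:i], valid[lo:i]
        with np.errstate(invalid="ignore"):
            at_baseline = (~backv) | (back >= baseline - onset_margin)
        relb = np.flatnonzero(at_baseline)
        onset = lo + (int(relb[-1]) if relb.size else 0)
        nadir_off = int(np.argmin(s[i:end + 1]))
        ev = DesaturationEvent(
            onset_s=onset / fs,
            nadir_s=(i + nadir_off) / fs,
            depth=float(baseline - s[i + nadir_off]),
            duration_s=(end - onset + 1) / fs,
        )
        if events and ev.onset_s < events[-1].onset_s + events[-1].duration_s:
            prev = events[-1]
            merged_end = max(prev.onset_s + prev.duration_s,
                             ev.onset_s + ev.duration_s)
            deeper = prev if prev.depth >= ev.depth else ev
            events[-1] = DesaturationEvent(
                onset_s=prev.onset_s,
                nadir_s=deeper.nadir_s,
                depth=max(prev.depth, ev.depth),
                duration_s=merged_end - prev.onset_s,
            )
        else:
            events.append(ev)
        consumed_until = end + 1
    return events


def desaturation_index(record: SpO2Record, min_drop: float = 4.0, **kwargs) -> float:
    """ODI of a record straight from the detector, in events/hour."""
    events = detect_desaturations(record, min_drop=min_drop, **kwargs)
    return compute_index(len(events), record.duration_s)
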