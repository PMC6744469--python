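"""Synthetic annotated oximetry cohorts.

Real ambulatory oximetry datasets with manually re-scored events are not
publicly distributable, so this module generates surrogate cohorts with a
known ground truth.  Each patient is summarised by a :class:`PatientProfile`
whose target AHI spans the full clinical range (0 to ~150 events/hour,
covering all four OSA severity classes).  A recording is produced by
planting non-overlapping respiratory events by a homogeneous Poisson
process, attaching a baseline-to-nadir desaturation to each event (a
circulation-delayed linear fall followed by an exponential-shaped
resaturation), then adding oximeter noise, integer quantization, and
flagged dropout artifacts.

The simulator emits only the SpO2 channel plus the planted annotations;
there is no airflow, effort, position, or sleep-stage structure.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .records import Event, EventAnnotation, SpO2Record

#: seconds between respiratory-event onset and the start of the associated
#: desaturation (circulation delay from lung to fingertip oximeter).
DESAT_LAG_S = 15.0

#: fraction of the recording that planted events may occupy before the
#: requested rate is declared infeasible.
_MAX_OCCUPANCY = 0.95

#: default severity mix: proportions of no/mild/moderate/severe OSA in a
#: suspected-OSA clinical population.
DEFAULT_SEVERITY_MIX = (0.486, 0.254, 0.129, 0.131)

_SEVERITY_AHI_EDGES = (0.0, 5.0, 15.0, 30.0)


@dataclass(frozen=True)
class PatientProfile:
    """Generative parameters for one synthetic patient.

    All events in a recording share the profile's event duration and
    resaturation time; the per-event variability lives in the desaturation
    depths.  ``desat_yield`` is the probability that a respiratory event
    produces a >= 4 percentage-point desaturation — events below that
    threshold still dent the trace but are not scored as desaturations,
    which is what makes ODI <= AHI.
    """

    target_ahi: float
    apnea_fraction: float = 0.15
    desat_yield: float = 0.85
    baseline_spo2: float = 96.5
    desat_depth_mean: float = 6.0
    desat_depth_sd: float = 1.5
    event_duration_s: float = 30.0
    resat_duration_s: float = 20.0
    noise_sd: float = 0.4
    artifact_rate: float = 0.5
    recording_duration_s: float = 28800.0

    def __post_init__(self) -> None:
        if not 0 <= self.target_ahi <= 150:
            raise ValueError(f"target_ahi must be in [0, 150], got {self.target_ahi}")
        if not 0 <= self.apnea_fraction <= 1:
            raise ValueError("apnea_fraction must be in [0, 1]")
        if not 0 <= self.desat_yield <= 1:
            raise ValueError("desat_yield must be in [0, 1]")
        if not 88 <= self.baseline_spo2 <= 99:
            raise ValueError("baseline_spo2 must be in [88, 99] %")
        if self.desat_depth_mean < 4:
            raise ValueError("desat_depth_mean must be >= 4 percentage points")
        if self.desat_depth_sd < 0:
            raise ValueError("desat_depth_sd must be >= 0")
        if not 10 <= self.event_duration_s <= 120:
            raise ValueError("event_duration_s must be in [10, 120] s")
        if self.resat_duration_s <= 0:
            raise ValueError("resat_duration_s must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.artifact_rate < 0:
            raise ValueError("artifact_rate must be >= 0")
        if self.recording_duration_s <= 0:
            raise ValueError("recording_duration_s must be > 0")


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               low: float, high: float, size: int) -> np.ndarray:
    """Truncated-normal draws by inverse-CDF so they stay generator-driven."""
    from scipy.stats import truncnorm

    if sd == 0:
        if not low <= mean <= high:
            raise ValueError("degenerate truncated normal outside bounds")
        return np.full(size, mean)
    a, b = (low - mean) / sd, (high - mean) / sd
    u = rng.uniform(size=size)
    return truncnorm.ppf(u, a, b, loc=mean, scale=sd)


def sample_cohort(n: int, severity_mix=DEFAULT_SEVERITY_MIX,
                  seed: int = 0) -> list[PatientProfile]:
    """Draw ``n`` patient profiles stratified over OSA severity classes.

    Parameters
    ----------
    n : int
        Cohort size (>= 1).
    severity_mix : sequence of 4 floats
        Proportions of (no OSA, mild, moderate, severe) patients; must sum
        to 1.  Each patient's class is drawn i.i.d. from this mix, so class
        counts are multinomial around ``n * mix``.
    seed : int
        Seed for all randomness.

    Returns
    -------
    list of PatientProfile
    """
    if n < 1:
        raise ValueError(f"cohort size must be >= 1, got {n}")
    mix = np.asarray(severity_mix, dtype=float)
    if mix.shape != (4,) or np.any(mix < 0) or abs(mix.sum() - 1.0) > 1e-9:
        raise ValueError(
            f"severity_mix must be 4 non-negative proportions summing to 1, got {severity_mix}"
        )
    rng = np.random.default_rng(seed)
    classes = rng.choice(4, size=n, p=mix)
    profiles = []
    for c in classes:
        # AHI within class: uniform inside the three bounded classes, a
        # decaying tail above 30 reaching the extreme clinical range ~150.
        if c == 0:
            ahi = rng.uniform(0.0, 5.0)
        elif c == 1:
            ahi = rng.uniform(5.0, 15.0)
        elif c == 2:
            ahi = rng.uniform(15.0, 30.0)
        else:
            ahi = 30.0 + rng.exponential(20.0)
            while ahi > 150.0:
                ahi = 30.0 + rng.exponential(20.0)

        # keep the event footprint below the mean inter-event interval so
        # high-rate nights remain feasible (severe OSA has short cycles)
        cycle = 3600.0 / max(ahi, 1.0)
        event_dur = float(np.clip(rng.uniform(15.0, 45.0), None, 0.45 * cycle))
        event_dur = max(event_dur, 10.0)
        resat = float(np.clip(20.0, 5.0, 0.35 * cycle))

        profiles.append(
            PatientProfile(
                target_ahi=float(ahi),
                apnea_fraction=float(rng.beta(2.0, 11.0)),
                desat_yield=float(rng.beta(8.5, 1.5)),
                baseline_spo2=float(_truncnorm(rng, 96.5, 1.0, 92.0, 99.0, 1)[0]),
                desat_depth_mean=float(rng.uniform(5.0, 10.0)),
                desat_depth_sd=float(rng.uniform(0.5, 2.0)),
                event_duration_s=event_dur,
                resat_duration_s=resat,
                noise_sd=float(rng.uniform(0.2, 0.6)),
                artifact_rate=float(rng.uniform(0.0, 1.0)),
                recording_duration_s=float(rng.uniform(21600.0, 32400.0)),
            )
        )
    return profiles


def severity_of_profile(profile: PatientProfile) -> int:
    """Index of the severity class (0..3) the profile's target AHI falls in."""
    return int(np.searchsorted(_SEVERITY_AHI_EDGES, profile.target_ahi, side="right")) - 1


def _draw_event_times(profile: PatientProfile, rng: np.random.Generator) -> np.ndarray:
    """Sample non-overlapping event onset times.

    The event count is Poisson at the target rate; onsets are then placed
    uniformly subject to a minimum gap equal to the event footprint
    (event + resaturation), which is the conditional law of a hard-core
    thinned Poisson process given the count.
    """
    T = profile.recording_duration_s
    rate_s = profile.target_ahi / 3600.0
    gap = profile.event_duration_s + profile.resat_duration_s
    if rate_s * gap > _MAX_OCCUPANCY:
        raise ValueError(
            f"event rate {profile.target_ahi:.1f}/hour with footprint {gap:.0f} s "
            f"cannot fit without overlap"
        )
    n = rng.poisson(rate_s * T)
    if n == 0:
        return np.empty(0)
    tail = DESAT_LAG_S + gap  # last event's desaturation must end inside the record
    free = T - tail - (n - 1) * gap
    if free <= 0:
        raise ValueError(
            f"drawn event count {n} at rate {profile.target_ahi:.1f}/hour "
            f"cannot fit without overlap in {T:.0f} s"
        )
    u = np.sort(rng.uniform(0.0, free, size=n))
    return u + gap * np.arange(n)


def simulate_record(profile: PatientProfile, seed: int = 0,
                    fs: float = 4.0) -> tuple[SpO2Record, EventAnnotation]:
    """Generate one annotated synthetic night.

    Returns the quantized SpO2 trace and the planted ground-truth events.
    Respiratory events are annotated at their onset; each desaturating
    event additionally yields a ``desaturation`` annotation starting at the
    (circulation-delayed) fall and spanning fall + resaturation.
    """
    rng = np.random.default_rng(seed)
    T = profile.recording_duration_s
    n_samp = int(round(fs * T))
    t = np.arange(n_samp) / fs

    onsets = _draw_event_times(profile, rng)
    n_ev = onsets.size

    kinds = np.where(rng.uniform(size=n_ev) < profile.apnea_fraction,
                     "apnea", "hypopnea")
    desaturating = rng.uniform(size=n_ev) < profile.desat_yield
    depths = np.empty(n_ev)
    n_deep = int(desaturating.sum())
    if n_deep:
        depths[desaturating] = _truncnorm(
            rng, profile.desat_depth_mean, profile.desat_depth_sd, 4.0, 30.0, n_deep)
    if n_ev - n_deep:
        depths[~desaturating] = _truncnorm(
            rng, profile.desat_depth_mean, profile.desat_depth_sd, 0.5,
            np.nextafter(4.0, 0.0), n_ev - n_deep)

    signal = np.full(n_samp, profile.baseline_spo2)
    fall, resat = profile.event_duration_s, profile.resat_duration_s
    # resaturation decays with time constant resat/3 and is shifted to
    # reach the baseline exactly at the end of the resaturation window
    e3 = np.exp(-3.0)
    for onset, depth in zip(onsets, depths):
        t0 = onset + DESAT_LAG_S          # fall start
        t1 = t0 + fall                    # nadir
        t2 = t1 + resat                   # back at baseline
        i0, i1, i2 = (int(np.ceil(x * fs)) for x in (t0, t1, t2))
        i2 = min(i2, n_samp)
        seg = t[i0:i1]
        signal[i0:i1] -= depth * (seg - t0) / fall
        seg = t[i1:i2]
        signal[i1:i2] -= depth * (np.exp(-3.0 * (seg - t1) / resat) - e3) / (1.0 - e3)

    if profile.noise_sd > 0:
        signal = signal + rng.normal(0.0, profile.noise_sd, size=n_samp)
    signal = np.clip(np.rint(signal), 1.0, 100.0)

    valid = np.ones(n_samp, dtype=bool)
    n_art = rng.poisson(profile.artifact_rate * T / 3600.0)
    for _ in range(n_art):
        start = rng.uniform(0.0, T)
        dur = rng.uniform(5.0, 30.0)
        j0 = int(start * fs)
        j1 = min(int((start + dur) * fs), n_samp)
        valid[j0:j1] = False
    signal[~valid] = np.nan

    events = [Event(str(k), float(o), float(fall)) for k, o in zip(kinds, onsets)]
    for onset, depth, deep in zip(onsets, depths, desaturating):
        if deep:
            events.append(Event("desaturation", float(onset + DESAT_LAG_S),
                                float(fall + resat)))
    return SpO2Record(samples=signal, fs=fs, valid=valid), EventAnnotation(events)


def write_cohort(profiles: list[PatientProfile], out_dir: str | Path,
                 seed: int = 0, fs: float = 4.0) -> dict:
    """Simulate every profile and write records, annotations and a manifest.

    Each patient ``i`` is simulated with seed ``seed + i`` and written as
    ``patient_<i>.csv`` / ``patient_<i>_events.csv``; the manifest JSON
    records profile parameters, per-patient seeds, and reference indices.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": seed, "fs": fs, "patients": []}
    for i, profile in enumerate(profiles):
        rec, ann = simulate_record(profile, seed=seed + i, fs=fs)
        rec_path = out / f"patient_{i:04d}.csv"
        ann_path = out / f"patient_{i:04d}_events.csv"
        rec.to_csv(rec_path)
        ann.to_csv(ann_path)
        manifest["patients"].append(
            {
                "id": f"patient_{i:04d}",
                "seed": seed + i,
                "record": rec_path.name,
                "annotation": ann_path.name,
                "profile": dataclasses.asdict(profile),
                "reference_ahi": ann.reference_ahi(rec.duration_s),
                "reference_odi": ann.reference_odi(rec.duration_s),
                "severity_class": severity_of_profile(profile),
            }
        )
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
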