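"""Reproducible end-to-end experiment: simulate -> train -> evaluate.

One :class:`RunConfig` fully determines every output byte: the synthetic
cohort, the train/validation/test split, both network trainings (AHI and
ODI), and the evaluation reports.  The default split strategy mirrors
clinical practice for building a representative test set: patients are
sorted by reference AHI and every k-th patient is assigned to the test
set, so the test set covers the full severity range; a purely random
split is available as an alternative.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .ann import TrainingConfig
from .evaluate import EvaluationReport
from .model import OximetryIndexModel, OximetryIndexResults
from .records import EventAnnotation, SpO2Record
from .simulator import DEFAULT_SEVERITY_MIX, sample_cohort, simulate_record


@dataclass
class RunConfig:
    """Everything needed to reproduce one experiment bit-for-bit."""

    n_train: int = 600
    n_val: int = 50
    n_test: int = 100
    severity_mix: tuple[float, float, float, float] = DEFAULT_SEVERITY_MIX
    seed: int = 0
    fs: float = 4.0
    split: str = "ahi_sorted"          # or "random"
    epoch_subsample: int = 50          # training-pool thinning (stride in epochs)
    window_s: float = 600.0
    overlap: float = 0.98
    target_fs: float = 0.5
    invalid_threshold: float = 0.10
    training: TrainingConfig = field(default_factory=lambda: TrainingConfig(
        max_iterations=800, max_val_failures=100))
    targets: tuple[str, ...] = ("ahi", "odi")

    def __post_init__(self) -> None:
        if self.split not in ("ahi_sorted", "random"):
            raise ValueError(f"unknown split strategy {self.split!r}")
        if min(self.n_train, self.n_val, self.n_test) < 1:
            raise ValueError("all cohort sizes must be >= 1")
        if isinstance(self.training, dict):
            self.training = TrainingConfig(**self.training)

    @property
    def n_total(self) -> int:
        return self.n_train + self.n_val + self.n_test

    def prep_kwargs(self) -> dict:
        return {
            "window_s": self.window_s,
            "overlap": self.overlap,
            "target_fs": self.target_fs,
            "invalid_threshold": self.invalid_threshold,
        }

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "severity_mix" in d:
            d["severity_mix"] = tuple(d["severity_mix"])
        if "targets" in d:
            d["targets"] = tuple(d["targets"])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class Cohort:
    """Simulated patients with their records, annotations and references."""

    records: list[SpO2Record]
    annotations: list[EventAnnotation]
    reference_ahi: np.ndarray
    reference_odi: np.ndarray
    patient_ids: list[str]

    def subset(self, idx: np.ndarray) -> "Cohort":
        return Cohort(
            records=[self.records[i] for i in idx],
            annotations=[self.annotations[i] for i in idx],
            reference_ahi=self.reference_ahi[idx],
            reference_odi=self.reference_odi[idx],
            patient_ids=[self.patient_ids[i] for i in idx],
        )

    def __len__(self) -> int:
        return len(self.records)


def generate_cohort(config: RunConfig) -> Cohort:
    """Simulate the full cohort; patient i gets seed ``seed*1000003 + i``."""
    profiles = sample_cohort(config.n_total, config.severity_mix,
                             seed=config.seed)
    base = (config.seed * 1000003) % (2**31)
    records, annotations, ahis, odis, ids = [], [], [], [], []
    for i, prof in enumerate(profiles):
        rec, ann = simulate_record(prof, seed=(base + i) % (2**31), fs=config.fs)
        records.append(rec)
        annotations.append(ann)
        ahis.append(ann.reference_ahi(rec.duration_s))
        odis.append(ann.reference_odi(rec.duration_s))
        ids.append(f"patient_{i:04d}")
    return Cohort(records, annotations, np.array(ahis), np.array(odis), ids)


def split_cohort(reference_ahi: np.ndarray, config: RunConfig,
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Train/validation/test indices under the configured strategy.

    ``ahi_sorted``: sort by reference AHI and take every k-th patient
    (k = n_total // n_test) into the test set, so the test set spans all
    severities; the validation set is then drawn at random from the rest.
    """
    n = reference_ahi.size
    if n != config.n_total:
        raise ValueError("reference vector does not match configured sizes")
    rng = np.random.default_rng(config.seed + 777)
    if config.split == "random":
        perm = rng.permutation(n)
        test = perm[:config.n_test]
        val = perm[config.n_test:config.n_test + config.n_val]
        train = perm[config.n_test + config.n_val:]
    else:
        order = np.argsort(reference_ahi, kind="stable")
        k = n // config.n_test
        test = order[(k - 1)::k][:config.n_test]
        rest = np.setdiff1d(order, test)
        val = rng.permutation(rest)[:config.n_val]
        train = np.setdiff1d(rest, val)
    return np.sort(train), np.sort(val), np.sort(test)


def run_experiment(config: RunConfig | None = None, verbose: bool = False,
                   ) -> dict:
    """Full pipeline; returns results, reports, and per-stage timings.

    Returns a dict with keys ``config``, ``split``, ``results`` (per-target
    :class:`OximetryIndexResults`), ``reports`` (per-target
    :class:`EvaluationReport`), and ``timings_s``.
    """
    config = config or RunConfig()
    timings: dict[str, float] = {}

    def log(msg: str) -> None:
        if verbose:
            print(json.dumps(msg) if isinstance(msg, dict) else msg, flush=True)

    t0 = time.perf_counter()
    cohort = generate_cohort(config)
    timings["simulate"] = time.perf_counter() - t0
    log(f"simulated {len(cohort)} patients in {timings['simulate']:.1f} s")

    train_idx, val_idx, test_idx = split_cohort(cohort.reference_ahi, config)
    train, val, test = (cohort.subset(i) for i in (train_idx, val_idx, test_idx))

    results: dict[str, OximetryIndexResults] = {}
    reports: dict[str, EvaluationReport] = {}
    for target in config.targets:
        t0 = time.perf_counter()
        model = OximetryIndexModel.from_records(
            train.records, train.annotations, val.records, val.annotations,
            target=target, epoch_subsample=config.epoch_subsample,
            **config.prep_kwargs())
        res = model.fit(dataclasses.replace(config.training))
        timings[f"train_{target}"] = time.perf_counter() - t0
        log(f"trained {target} network: {len(res.history.train_mse)} iterations "
            f"in {timings[f'train_{target}']:.1f} s ({res.history.stop_reason})")
        t0 = time.perf_counter()
        reports[target] = res.evaluate(test.records, test.annotations,
                                       patient_ids=test.patient_ids)
        timings[f"evaluate_{target}"] = time.perf_counter() - t0
        results[target] = res
        log(reports[target].summary())

    return {
        "config": config,
        "split": {"train": train_idx, "val": val_idx, "test": test_idx},
        "cohort": cohort,
        "results": results,
        "reports": reports,
        "timings_s": timings,
    }
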