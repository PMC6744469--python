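"""Model/Results interface over the epoch-regression machinery.

:class:`OximetryIndexModel` is constructed from pooled training and
validation epoch sets (or directly from records + annotations) for one
target index, AHI or ODI; ``fit()`` runs SCG training with early stopping
and returns an :class:`OximetryIndexResults` carrying the trained network,
the training history, and evaluation/prediction methods.  The AHI and ODI
networks of a full experiment are simply two independent instances of this
pair fitted with different targets.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .ann import (MLPModel, TrainingConfig, TrainingHistory, fit_normalization,
                  init_model, scg_train)
from .evaluate import EvaluationReport, PatientEstimate, estimate_night
from .preprocess import EpochSet, pool_training_epochs
from .records import EventAnnotation, SpO2Record

DEFAULT_LAYER_SIZES = (300, 60, 15, 5, 1)


class OximetryIndexModel:
    """Epoch-to-index regression model for one target (AHI or ODI).

    Parameters
    ----------
    train_epochs, val_epochs : EpochSet
        Pooled epoch sets with targets attached (see
        :func:`oxinet.preprocess.pool_training_epochs`).
    target : {"ahi", "odi"}
        Which per-epoch target column to regress on.
    layer_sizes : tuple of int
        Network architecture, input to output.  The default is the
        300-input, 60/15/5 hidden, scalar-output geometry.
    """

    def __init__(self, train_epochs: EpochSet, val_epochs: EpochSet,
                 target: str = "ahi",
                 layer_sizes: tuple[int, ...] = DEFAULT_LAYER_SIZES,
                 prep_kwargs: dict | None = None):
        if target not in ("ahi", "odi"):
            raise ValueError(f"target must be 'ahi' or 'odi', got {target!r}")
        self.target = target
        self.layer_sizes = tuple(layer_sizes)
        self.prep_kwargs = dict(prep_kwargs or {})
        self.train_inputs = train_epochs.epochs
        self.val_inputs = val_epochs.epochs
        self.train_targets = self._targets_of(train_epochs)
        self.val_targets = self._targets_of(val_epochs)
        if self.train_inputs.shape[0] == 0:
            raise ValueError("empty training epoch set")
        if self.train_inputs.shape[1] != self.layer_sizes[0]:
            raise ValueError(
                f"epoch length {self.train_inputs.shape[1]} does not match "
                f"network input size {self.layer_sizes[0]}"
            )

    def _targets_of(self, es: EpochSet) -> np.ndarray:
        t = es.target_ahi if self.target == "ahi" else es.target_odi
        if t is None:
            raise ValueError(f"epoch set lacks {self.target} targets")
        return np.asarray(t, dtype=float)

    @classmethod
    def from_records(cls, train_records: list[SpO2Record],
                     train_annotations: list[EventAnnotation],
                     val_records: list[SpO2Record],
                     val_annotations: list[EventAnnotation],
                     target: str = "ahi", epoch_subsample: int = 1,
                     layer_sizes: tuple[int, ...] = DEFAULT_LAYER_SIZES,
                     **prep_kwargs) -> "OximetryIndexModel":
        """Build the model straight from annotated records."""
        train = pool_training_epochs(train_records, train_annotations,
                                     epoch_subsample=epoch_subsample, **prep_kwargs)
        val = pool_training_epochs(val_records, val_annotations,
                                   epoch_subsample=epoch_subsample, **prep_kwargs)
        return cls(train, val, target=target, layer_sizes=layer_sizes,
                   prep_kwargs=prep_kwargs)

    def fit(self, config: TrainingConfig | None = None) -> "OximetryIndexResults":
        """Initialise, normalize, and train the network by SCG."""
        config = config or TrainingConfig()
        mlp = init_model(self.layer_sizes, seed=config.seed)
        mlp.input_norm, mlp.target_norm = fit_normalization(
            self.train_inputs, self.train_targets)
        mlp, history = scg_train(mlp, self.train_inputs, self.train_targets,
                                 self.val_inputs, self.val_targets, config)
        return OximetryIndexResults(self, mlp, history, config)


@dataclass
class OximetryIndexResults:
    """Fitted network plus training history and evaluation methods."""

    model: OximetryIndexModel
    mlp: MLPModel
    history: TrainingHistory
    config: TrainingConfig

    @property
    def target(self) -> str:
        return self.model.target

    def predict_epochs(self, epochs: np.ndarray) -> np.ndarray:
        """Per-epoch events/hour predictions (clamped at 0)."""
        return self.mlp.predict(epochs)

    def estimate_night(self, record: SpO2Record) -> float:
        """Full-night index estimate for one record."""
        return estimate_night(self.mlp, record, **self.model.prep_kwargs)

    def evaluate(self, records: list[SpO2Record],
                 annotations: list[EventAnnotation],
                 patient_ids: list[str] | None = None) -> EvaluationReport:
        """Estimate every test night and compile the evaluation report."""
        if len(records) != len(annotations):
            raise ValueError("records/annotations length mismatch")
        ids = patient_ids or [f"patient_{i:04d}" for i in range(len(records))]
        estimates = []
        for pid, rec, ann in zip(ids, records, annotations):
            ref = (ann.reference_ahi(rec.duration_s) if self.target == "ahi"
                   else ann.reference_odi(rec.duration_s))
            estimates.append(PatientEstimate(pid, ref, self.estimate_night(rec)))
        return EvaluationReport.from_estimates(estimates, index_name=self.target)

    def save(self, path: str | Path) -> None:
        self.mlp.save(path)

    def summary(self) -> str:
        h = self.history
        n_iter = len(h.train_mse)
        lines = [
            f"Oximetry index regression — target {self.target.upper()}",
            "-" * 56,
            f"architecture            {' -> '.join(map(str, self.model.layer_sizes))}",
            f"training epochs         {self.model.train_inputs.shape[0]}",
            f"validation epochs       {self.model.val_inputs.shape[0]}",
            f"SCG iterations run      {n_iter}",
            f"best validation iter    {h.best_iteration + 1}",
            f"best validation MSE     {h.best_val_mse:.6g} (normalized)",
            f"final training MSE      {h.train_mse[-1] if h.train_mse else float('nan'):.6g}"
            " (normalized)",
            f"stop reason             {h.stop_reason}",
        ]
        return "\n".join(lines)
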