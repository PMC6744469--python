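"""Full-night index estimation and the cohort evaluation battery.

A night's AHI (or ODI) estimate is the arithmetic mean of the network's
predictions over all valid 10-minute epochs of the record.  Cohort
evaluation mirrors standard agreement reporting between an automatic
method and manual scoring: absolute-error statistics, a 4x4 severity
confusion matrix with classification accuracy, the same error statistics
restricted to misclassified patients, and a two-way random-effects
absolute-agreement single-rater intraclass correlation (ICC(2,1)) with a
95% F-based confidence interval.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .ann import MLPModel
from .preprocess import preprocess_record
from .records import SpO2Record
from .scoring import SEVERITY_LABELS, SeverityCategory, classify_severity


@dataclass
class PatientEstimate:
    """Reference vs estimated index (events/hour) for one patient."""

    patient_id: str
    reference_index: float
    estimated_index: float

    def __post_init__(self) -> None:
        if self.estimated_index < 0:
            raise ValueError("estimated index must be non-negative")

    @property
    def reference_class(self) -> SeverityCategory:
        return classify_severity(self.reference_index)

    @property
    def estimated_class(self) -> SeverityCategory:
        return classify_severity(self.estimated_index)


def estimate_night(model: MLPModel, record: SpO2Record, **prep_kwargs) -> float:
    """Full-night events/hour estimate: mean over valid-epoch predictions.

    The mean is taken over the raw (unclamped) per-epoch outputs and the
    night-level index is then clamped at 0: clamping each epoch before
    averaging would bias low-index nights upward, since near-zero epoch
    predictions scatter on both sides of zero.
    """
    es = preprocess_record(record, annotation=None, **prep_kwargs)
    if not es.valid_mask.any():
        raise ValueError("record has no valid epochs to predict from")
    x = es.epochs[es.valid_mask]
    if model.input_norm is None or model.target_norm is None:
        raise ValueError("normalization parameters are not fitted")
    yh = model.forward_normalized(model.input_norm.transform(x))
    preds = model.target_norm.inverse(yh)[:, 0]
    return float(max(np.mean(preds), 0.0))


def _median(x: np.ndarray) -> float:
    """Median with the midpoint-of-middle-two convention for even n."""
    return float(np.median(x))


def error_metrics(estimates: list[PatientEstimate]) -> dict:
    """Absolute- and percentage-error statistics over a cohort.

    Percentage error is undefined at a zero reference; patients with
    reference 0 are excluded from the percentage-error median only (they
    stay in the absolute-error statistics), and the number excluded is
    reported.
    """
    if not estimates:
        raise ValueError("empty estimate list")
    ref = np.array([e.reference_index for e in estimates])
    est = np.array([e.estimated_index for e in estimates])
    abs_err = np.abs(est - ref)
    nonzero = ref > 0
    pct = 100.0 * abs_err[nonzero] / ref[nonzero]
    return {
        "n": len(estimates),
        "mean_abs_error": float(abs_err.mean()),
        "median_abs_error": _median(abs_err),
        "min_error": float(abs_err.min()),
        "max_error": float(abs_err.max()),
        "median_pct_error": _median(pct) if pct.size else float("nan"),
        "n_excluded_from_pct": int((~nonzero).sum()),
    }


def classification_metrics(estimates: list[PatientEstimate]) -> dict:
    """Severity confusion matrix (reference rows, estimate columns) + accuracy."""
    if not estimates:
        raise ValueError("empty estimate list")
    confusion = np.zeros((4, 4), dtype=int)
    for e in estimates:
        confusion[int(e.reference_class), int(e.estimated_class)] += 1
    n = len(estimates)
    n_correct = int(np.trace(confusion))
    misclassified = [e for e in estimates if e.reference_class != e.estimated_class]
    out = {
        "confusion": confusion,
        "confusion_labels": list(SEVERITY_LABELS),
        "accuracy": n_correct / n,
        "n_misclassified": n - n_correct,
    }
    if misclassified:
        sub = error_metrics(misclassified)
        out["misclassified_errors"] = {
            k: sub[k] for k in ("mean_abs_error", "median_abs_error",
                                "median_pct_error")
        }
    else:
        out["misclassified_errors"] = None
    return out


def icc_agreement(x, y, confidence: float = 0.95) -> tuple[float, float, float]:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    The n subjects are crossed with k=2 raters (manual reference and the
    network); from the two-way ANOVA mean squares,

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    The confidence interval uses the standard F-based bounds with a
    Satterthwaite approximation for the denominator degrees of freedom.

    Returns (icc, ci_low, ci_high).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 paired measurements, got {n}")
    k = 2
    table = np.column_stack([x, y])
    grand = table.mean()
    row_means = table.mean(axis=1)
    col_means = table.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sse = np.sum((table - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        raise ValueError("degenerate (constant) measurements: ICC undefined")
    icc = (msr - mse) / denom

    alpha = 1.0 - confidence
    a = k * icc / (n * (1.0 - icc)) if icc < 1.0 else np.inf
    b = 1.0 + k * icc * (n - 1.0) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
    if np.isfinite(a) and mse > 0:
        v = ((a * msc + b * mse) ** 2
             / ((a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))))
        f_l = stats.f.ppf(1.0 - alpha / 2, n - 1, v)
        f_u = stats.f.ppf(1.0 - alpha / 2, v, n - 1)
        lower = (n * (msr - f_l * mse)
                 / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr))
        upper = (n * (f_u * msr - mse)
                 / (k * msc + (k * n - k - n) * mse + n * f_u * msr))
    else:  # perfect agreement: interval collapses
        lower = upper = icc
    return float(icc), float(lower), float(upper)


@dataclass
class EvaluationReport:
    """Complete per-cohort evaluation of one network (AHI or ODI)."""

    index_name: str
    estimates: list[PatientEstimate]
    errors: dict
    classification: dict
    icc: float
    icc_ci: tuple[float, float]

    @classmethod
    def from_estimates(cls, estimates: list[PatientEstimate],
                       index_name: str = "ahi") -> "EvaluationReport":
        ref = [e.reference_index for e in estimates]
        est = [e.estimated_index for e in estimates]
        icc, lo, hi = icc_agreement(ref, est)
        return cls(
            index_name=index_name,
            estimates=estimates,
            errors=error_metrics(estimates),
            classification=classification_metrics(estimates),
            icc=icc,
            icc_ci=(lo, hi),
        )

    def to_dict(self) -> dict:
        cls = dict(self.classification)
        cls["confusion"] = self.classification["confusion"].tolist()
        return {
            "index": self.index_name,
            "n": self.errors["n"],
            "errors": self.errors,
            "classification": cls,
            "icc": self.icc,
            "icc_ci_95": list(self.icc_ci),
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    def estimates_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": [e.patient_id for e in self.estimates],
                "reference": [e.reference_index for e in self.estimates],
                "estimate": [e.estimated_index for e in self.estimates],
                "ref_class": [e.reference_class.label for e in self.estimates],
                "est_class": [e.estimated_class.label for e in self.estimates],
            }
        )

    def estimates_to_csv(self, path: str | Path) -> None:
        self.estimates_frame().to_csv(path, index=False, float_format="%.10g")

    def summary(self) -> str:
        """Formatted text report (error table, accuracy, confusion, ICC)."""
        e = self.errors
        c = self.classification
        lines = [
            f"Evaluation report — {self.index_name.upper()} "
            f"(N = {e['n']} patients)",
            "-" * 56,
            f"mean absolute error (events/hour)    {e['mean_abs_error']:8.2f}",
            f"median absolute error (events/hour)  {e['median_abs_error']:8.2f}",
            f"min error (events/hour)              {e['min_error']:8.2f}",
            f"max error (events/hour)              {e['max_error']:8.2f}",
            f"median % error                       {e['median_pct_error']:8.1f}",
            f"classification accuracy              {100 * c['accuracy']:8.1f}%",
            f"misclassified patients               {c['n_misclassified']:8d}",
        ]
        if c["misclassified_errors"]:
            m = c["misclassified_errors"]
            lines += [
                f"misclassified: mean absolute error   {m['mean_abs_error']:8.2f}",
                f"misclassified: median absolute error {m['median_abs_error']:8.2f}",
                f"misclassified: median % error        {m['median_pct_error']:8.1f}",
            ]
        lines.append(
            f"ICC (2,1)                            {self.icc:8.3f} "
            f"(95% CI {self.icc_ci[0]:.3f}-{self.icc_ci[1]:.3f})"
        )
        lines.append("")
        lines.append("Confusion matrix (rows: reference, cols: estimate)")
        header = "            " + "".join(f"{l:>10}" for l in SEVERITY_LABELS)
        lines.append(header)
        for i, lab in enumerate(SEVERITY_LABELS):
            row = "".join(f"{self.classification['confusion'][i, j]:>10d}"
                          for j in range(4))
            lines.append(f"{lab:>12}{row}")
        return "\n".join(lines)
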