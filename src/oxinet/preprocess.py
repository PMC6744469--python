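"""Epoch extraction: full-night SpO2 traces to fixed-size network inputs.

A night is cut into 10-minute epochs with 98% overlap (stride 12 s) after
block-mean downsampling from the native 4 Hz to 0.5 Hz, giving 300 samples
per epoch.  Per-epoch regression targets are expressed in events/hour:
6 x the number of event onsets inside the 10-minute window, so that the
epoch-mean aggregation at prediction time directly yields a full-night
index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .records import EventAnnotation, RESPIRATORY_KINDS, SpO2Record

WINDOW_S = 600.0
OVERLAP = 0.98
TARGET_FS = 0.5
#: fraction of invalid samples above which an epoch is unusable
INVALID_EPOCH_THRESHOLD = 0.10


@dataclass
class EpochSet:
    """A matrix of fixed-length downsampled epochs with optional targets."""

    epochs: np.ndarray                     # (n_epochs, window_samples)
    epoch_start_s: np.ndarray              # (n_epochs,)
    valid_mask: np.ndarray                 # (n_epochs,) bool
    window_s: float = WINDOW_S
    stride_s: float = field(default=12.0)
    target_ahi: np.ndarray | None = None   # events/hour
    target_odi: np.ndarray | None = None
    record_id: np.ndarray | None = None    # provenance after pooling

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    def to_table(self, path: str | Path) -> None:
        """Write one row per epoch: start, validity, targets, 300 samples."""
        cols = {"epoch_start_s": self.epoch_start_s, "valid": self.valid_mask.astype(int)}
        if self.record_id is not None:
            cols["record_id"] = self.record_id
        if self.target_ahi is not None:
            cols["target_ahi"] = self.target_ahi
        if self.target_odi is not None:
            cols["target_odi"] = self.target_odi
        df = pd.DataFrame(cols)
        sample_cols = pd.DataFrame(
            self.epochs, columns=[f"s{j}" for j in range(self.epochs.shape[1])]
        )
        pd.concat([df, sample_cols], axis=1).to_csv(path, index=False,
                                                    float_format="%.10g")

    def save_npz(self, path: str | Path) -> None:
        """Compressed binary container for training-scale epoch sets."""
        arrays = {
            "epochs": self.epochs,
            "epoch_start_s": self.epoch_start_s,
            "valid_mask": self.valid_mask,
            "window_s": np.array(self.window_s),
            "stride_s": np.array(self.stride_s),
        }
        for name in ("target_ahi", "target_odi", "record_id"):
            val = getattr(self, name)
            if val is not None:
                arrays[name] = val
        np.savez_compressed(path, **arrays)

    @classmethod
    def load_npz(cls, path: str | Path) -> "EpochSet":
        with np.load(path, allow_pickle=False) as z:
            kw = {k: z[k] for k in ("target_ahi", "target_odi", "record_id") if k in z}
            return cls(
                epochs=z["epochs"],
                epoch_start_s=z["epoch_start_s"],
                valid_mask=z["valid_mask"].astype(bool),
                window_s=float(z["window_s"]),
                stride_s=float(z["stride_s"]),
                **kw,
            )


def downsample(record: SpO2Record, target_fs: float = TARGET_FS) -> SpO2Record:
    """Block-mean decimation (each output sample averages fs/target_fs inputs).

    Averaging doubles as the anti-alias step and suppresses oximeter
    quantization noise.  Any invalid input sample invalidates its whole
    output block.  A trailing partial block is discarded.
    """
    ratio = record.fs / target_fs
    if abs(ratio - round(ratio)) > 1e-9 or ratio < 1:
        raise ValueError(
            f"sampling rate {record.fs} Hz is not an integer multiple of "
            f"target rate {target_fs} Hz"
        )
    k = int(round(ratio))
    n_out = record.n_samples // k
    blocks = record.samples[: n_out * k].reshape(n_out, k)
    vblocks = record.valid[: n_out * k].reshape(n_out, k)
    out_valid = vblocks.all(axis=1)
    out = blocks.mean(axis=1)
    out[~out_valid] = np.nan
    return SpO2Record(samples=out, fs=target_fs, valid=out_valid)


def _fill_invalid(samples: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Linear interpolation across invalid runs (edges held at nearest valid)."""
    if valid.all():
        return samples
    if not valid.any():
        raise ValueError("record contains no valid samples")
    idx = np.arange(samples.size)
    out = samples.copy()
    out[~valid] = np.interp(idx[~valid], idx[valid], samples[valid])
    return out


def epoch_signal(record: SpO2Record, window_s: float = WINDOW_S,
                 overlap: float = OVERLAP,
                 invalid_threshold: float = INVALID_EPOCH_THRESHOLD) -> EpochSet:
    """Cut a (downsampled) record into overlapping fixed-length epochs.

    The stride is ``window_s * (1 - overlap)`` (12 s for the default
    10-minute window at 98% overlap); a final partial window is discarded.
    Epochs whose invalid-sample fraction exceeds ``invalid_threshold`` are
    flagged out in ``valid_mask``; remaining invalid samples are filled by
    linear interpolation so every retained epoch is fully numeric.
    """
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    win_n = int(round(window_s * record.fs))
    stride_n = int(round(window_s * (1.0 - overlap) * record.fs))
    if stride_n < 1:
        raise ValueError("stride below one sample; reduce overlap")
    if record.n_samples < win_n:
        raise ValueError(
            f"record duration {record.duration_s:.0f} s shorter than one "
            f"{window_s:.0f} s window"
        )
    filled = _fill_invalid(record.samples, record.valid)
    windows = np.lib.stride_tricks.sliding_window_view(filled, win_n)[::stride_n]
    # per-epoch invalid fraction via cumulative sum
    cs = np.concatenate([[0], np.cumsum(~record.valid)])
    starts = np.arange(windows.shape[0]) * stride_n
    invalid_frac = (cs[starts + win_n] - cs[starts]) / win_n
    return EpochSet(
        epochs=np.ascontiguousarray(windows, dtype=float),
        epoch_start_s=starts / record.fs,
        valid_mask=invalid_frac <= invalid_threshold,
        window_s=window_s,
        stride_s=stride_n / record.fs,
    )


def compute_epoch_targets(annotation: EventAnnotation, epoch_set: EpochSet,
                          kind: str = "ahi") -> EpochSet:
    """Attach per-epoch AHI or ODI targets, in events/hour.

    An event is assigned to every epoch whose window contains its onset
    (with 98% overlap an event typically contributes to ~50 epochs); the
    per-epoch index is the onset count scaled to an hourly rate
    (x 3600 / window_s, i.e. x 6 for 10-minute windows).
    """
    if kind not in ("ahi", "odi"):
        raise ValueError(f"kind must be 'ahi' or 'odi', got {kind!r}")
    kinds = RESPIRATORY_KINDS if kind == "ahi" else ("desaturation",)
    onsets = np.sort(annotation.onsets(kinds))
    starts = epoch_set.epoch_start_s
    counts = (np.searchsorted(onsets, starts + epoch_set.window_s, side="left")
              - np.searchsorted(onsets, starts, side="left"))
    targets = counts * (3600.0 / epoch_set.window_s)
    if kind == "ahi":
        epoch_set.target_ahi = targets
    else:
        epoch_set.target_odi = targets
    return epoch_set


def preprocess_record(record: SpO2Record, annotation: EventAnnotation | None = None,
                      target_fs: float = TARGET_FS, window_s: float = WINDOW_S,
                      overlap: float = OVERLAP,
                      invalid_threshold: float = INVALID_EPOCH_THRESHOLD) -> EpochSet:
    """Downsample, epoch, and (if an annotation is given) attach both targets."""
    low = downsample(record, target_fs) if record.fs != target_fs else record
    es = epoch_signal(low, window_s=window_s, overlap=overlap,
                      invalid_threshold=invalid_threshold)
    if annotation is not None:
        compute_epoch_targets(annotation, es, "ahi")
        compute_epoch_targets(annotation, es, "odi")
    return es


def pool_training_epochs(records: list[SpO2Record],
                         annotations: list[EventAnnotation],
                         epoch_subsample: int = 1,
                         **prep_kwargs) -> EpochSet:
    """Concatenate per-record epoch sets into one training matrix.

    Invalid epochs are excluded; provenance is kept in ``record_id``.
    ``epoch_subsample`` keeps every k-th epoch of each record — with 98%
    overlap adjacent epochs share 98% of their samples, so thinning the
    pool sacrifices little information while shrinking the training set.
    """
    if len(records) != len(annotations):
        raise ValueError(
            f"got {len(records)} records but {len(annotations)} annotations"
        )
    if not records:
        return EpochSet(
            epochs=np.empty((0, int(WINDOW_S * TARGET_FS))),
            epoch_start_s=np.empty(0),
            valid_mask=np.empty(0, dtype=bool),
        )
    parts, starts, ids, t_ahi, t_odi = [], [], [], [], []
    for i, (rec, ann) in enumerate(zip(records, annotations)):
        es = preprocess_record(rec, ann, **prep_kwargs)
        keep = np.flatnonzero(es.valid_mask)[::epoch_subsample]
        parts.append(es.epochs[keep])
        starts.append(es.epoch_start_s[keep])
        ids.append(np.full(keep.size, i))
        t_ahi.append(es.target_ahi[keep])
        t_odi.append(es.target_odi[keep])
    pooled = EpochSet(
        epochs=np.concatenate(parts),
        epoch_start_s=np.concatenate(starts),
        valid_mask=np.ones(sum(p.shape[0] for p in parts), dtype=bool),
        target_ahi=np.concatenate(t_ahi),
        target_odi=np.concatenate(t_odi),
        record_id=np.concatenate(ids),
    )
    return pooled
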