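"""In-memory containers shared by every pipeline stage.

The unit of inter-patient splitting is the :class:`ECGRecord` (one
multi-lead recording belonging to one patient); the unit of
classification is the :class:`BeatSegment` (one windowed, detrended
per-lead beat).  A :class:`SegmentTable` is the tabular collection of
segments that classifiers and report writers consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError

#: Canonical class labels, in the fixed order used by confusion matrices.
LABELS = ("NOR", "MI")


@dataclass
class ECGRecord:
    """A multi-lead ECG recording from a single patient.

    Parameters
    ----------
    signal : ndarray, shape (n_leads, n_samples)
        Per-lead traces, in normalized amplitude units.
    fs : float
        Sampling rate in Hz.
    patient_id : str
        Opaque patient identifier; drives inter-patient splitting.
    label : str
        Diagnostic class, one of ``LABELS``.
    lead_names : tuple of str
        One name per row of ``signal``.
    r_peaks : ndarray or None
        Ground-truth R-peak sample indices when the record is synthetic.
    """

    signal: np.ndarray
    fs: float
    patient_id: str
    label: str
    lead_names: tuple[str, ...] = ()
    r_peaks: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise InvalidArgumentError("signal must be 2-D (n_leads, n_samples)")
        if self.fs <= 0:
            raise InvalidArgumentError(f"fs must be positive, got {self.fs}")
        if self.label not in LABELS:
            raise InvalidArgumentError(f"label must be one of {LABELS}, got {self.label!r}")
        if not self.lead_names:
            self.lead_names = tuple(f"L{i}" for i in range(self.signal.shape[0]))
        if len(self.lead_names) != self.signal.shape[0]:
            raise InvalidArgumentError("lead_names length must match signal rows")

    @property
    def n_leads(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class BeatSegment:
    """One windowed per-lead beat, the classifier feature vector."""

    samples: np.ndarray
    lead_id: str
    patient_id: str
    class_label: str
    r_peak_index: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise InvalidArgumentError("segment samples must be 1-D")


class SegmentTable:
    """A feature matrix plus per-row metadata for a set of beat segments.

    ``X`` has one row per segment; ``meta`` carries ``patient_id``,
    ``lead_id``, ``label`` and ``r_peak`` columns aligned with ``X``.
    """

    META_COLUMNS = ("patient_id", "lead_id", "label", "r_peak")

    def __init__(self, X: np.ndarray, meta: pd.DataFrame):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise InvalidArgumentError("X must be 2-D")
        if len(meta) != X.shape[0]:
            raise InvalidArgumentError("meta rows must match X rows")
        missing = set(self.META_COLUMNS) - set(meta.columns)
        if missing:
            raise InvalidArgumentError(f"meta missing columns: {sorted(missing)}")
        self.X = X
        self.meta = meta.reset_index(drop=True)

    # -- construction -------------------------------------------------
    @classmethod
    def from_segments(cls, segments: Iterable[BeatSegment]) -> "SegmentTable":
        segs = list(segments)
        if segs:
            X = np.stack([s.samples for s in segs])
        else:
            X = np.empty((0, 0))
        meta = pd.DataFrame(
            {
                "patient_id": [s.patient_id for s in segs],
                "lead_id": [s.lead_id for s in segs],
                "label": [s.class_label for s in segs],
                "r_peak": [s.r_peak_index for s in segs],
            }
        )
        return cls(X, meta)

    @classmethod
    def concat(cls, tables: Sequence["SegmentTable"]) -> "SegmentTable":
        tables = [t for t in tables if len(t) > 0]
        if not tables:
            return cls(np.empty((0, 0)), pd.DataFrame(columns=list(cls.META_COLUMNS)))
        X = np.vstack([t.X for t in tables])
        meta = pd.concat([t.meta for t in tables], ignore_index=True)
        return cls(X, meta)

    # -- basic protocol ----------------------------------------------
    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def labels(self) -> np.ndarray:
        return self.meta["label"].to_numpy()

    @property
    def patient_ids(self) -> np.ndarray:
        return self.meta["patient_id"].to_numpy()

    def subset(self, index) -> "SegmentTable":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return SegmentTable(self.X[index], self.meta.iloc[index])

    def with_features(self, X: np.ndarray) -> "SegmentTable":
        """Same metadata, replaced feature matrix (e.g. after contamination)."""
        return SegmentTable(X, self.meta)

    # -- persistence ---------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        feat = pd.DataFrame(self.X, columns=[f"s{i}" for i in range(self.X.shape[1])])
        return pd.concat([self.meta, feat], axis=1)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SegmentTable":
        frame = pd.read_csv(path)
        meta = frame[list(cls.META_COLUMNS)]
        X = frame.drop(columns=list(cls.META_COLUMNS)).to_numpy(dtype=float)
        return cls(X, meta)

    def to_npz(self, path: str | Path) -> None:
        cols = {}
        for c in self.META_COLUMNS:
            arr = self.meta[c].to_numpy()
            cols[c] = arr.astype(str) if arr.dtype == object else arr
        np.savez(path, X=self.X, **cols)

    @classmethod
    def from_npz(cls, path: str | Path) -> "SegmentTable":
        with np.load(path, allow_pickle=False) as data:
            meta = pd.DataFrame({c: data[c] for c in cls.META_COLUMNS})
            return cls(data["X"], meta)
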