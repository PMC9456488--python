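"""Inter-patient evaluation: splits, metrics, and the robustness sweep.

The inter-patient paradigm assigns whole patients to either the
training group (G1) or the held-out group (G2); no patient contributes
beats to both sides, which prevents identity leakage and the
optimistic estimates of beat-level (intra-patient) splitting.  Within
G2, segments are divided 20%/80% into validation and test, stratified
by class.

Metrics follow the usual confusion-matrix definitions: per-class
precision TP/(TP+FP), recall TP/(TP+FN), F1 = 2PR/(P+R), and overall
accuracy (TP+TN)/(TP+TN+FP+FN).  Values for table comparison are
rounded half-up to 2 decimals; raw doubles are retained everywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import train_test_split

from . import noise as noise_mod
from . import synth
from .classify import predict
from .containers import LABELS, SegmentTable
from .errors import InvalidArgumentError, InvalidStateError

__all__ = [
    "SplitSpec", "SplitResult", "ConfusionMatrix", "MetricsRecord",
    "round_half_up", "inter_patient_split", "split_patients",
    "metrics_from_confusion", "normalize_confusion", "robustness_sweep",
    "RobustnessReport",
]

log = logging.getLogger(__name__)


def round_half_up(value: float, decimals: int = 2) -> float:
    """Decimal half-up rounding (0.735 → 0.74), as used in printed tables."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(f"{value:.12f}").quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class SplitSpec:
    """Inter-patient group sizes and the G2 validation/test fractions."""

    g1_patients_per_class: int = 27
    g2_patients_per_class: int = 26
    validation_fraction: float = 0.20
    test_fraction: float = 0.80
    seed: int = 0

    def __post_init__(self):
        if self.g1_patients_per_class < 1 or self.g2_patients_per_class < 1:
            raise InvalidArgumentError("group sizes must be >= 1")
        if abs(self.validation_fraction + self.test_fraction - 1.0) > 1e-12:
            raise InvalidArgumentError("validation and test fractions must sum to 1")


@dataclass
class SplitResult:
    """Patient groups plus the three segment sets of one split."""

    g1_patients: dict[str, list[str]]   # class -> patient ids
    g2_patients: dict[str, list[str]]
    train: SegmentTable
    validation: SegmentTable
    test: SegmentTable

    def assert_inter_patient(self) -> None:
        """Machine check of the defining property: G1 ∩ G2 = ∅ at segment level."""
        train_ids = set(self.train.patient_ids)
        held_out = set(self.validation.patient_ids) | set(self.test.patient_ids)
        overlap = train_ids & held_out
        if overlap:
            raise InvalidStateError(f"inter-patient violation: {sorted(overlap)}")

    def lead_record_counts(self, n_leads: int) -> dict[str, int]:
        """Per-class count of G1 lead-records (patients × leads)."""
        return {label: len(ids) * n_leads for label, ids in self.g1_patients.items()}


def split_patients(
    patients_by_class: dict[str, list[str]], spec: SplitSpec
) -> tuple[dict[str, list[str]], dict[str, list[str]]]:
    """Seeded assignment of patient ids to G1 (train) and G2 (held out)."""
    rng = np.random.default_rng(spec.seed)
    g1: dict[str, list[str]] = {}
    g2: dict[str, list[str]] = {}
    need = spec.g1_patients_per_class + spec.g2_patients_per_class
    for label, ids in patients_by_class.items():
        if len(ids) < need:
            raise InvalidArgumentError(
                f"class {label}: need {need} patients, have {len(ids)}"
            )
        order = list(ids)
        rng.shuffle(order)
        g1[label] = sorted(order[: spec.g1_patients_per_class])
        g2[label] = sorted(
            order[spec.g1_patients_per_class: need]
        )
    return g1, g2


def inter_patient_split(segments: SegmentTable, spec: SplitSpec) -> SplitResult:
    """Split a segment table into train / validation / test sets.

    Patients are grouped per class and assigned to G1 or G2 with the
    spec's seed; G2 segments are then divided into validation and test
    at the spec's fractions, stratified by class.  The inter-patient
    property is asserted before returning.
    """
    meta = segments.meta
    patients_by_class = {
        label: sorted(meta.loc[meta["label"] == label, "patient_id"].unique())
        for label in LABELS
    }
    g1, g2 = split_patients(patients_by_class, spec)
    g1_all = {p for ids in g1.values() for p in ids}
    g2_all = {p for ids in g2.values() for p in ids}

    in_g1 = meta["patient_id"].isin(g1_all).to_numpy()
    in_g2 = meta["patient_id"].isin(g2_all).to_numpy()
    train = segments.subset(in_g1)
    g2_segments = segments.subset(in_g2)

    idx = np.arange(len(g2_segments))
    val_idx, test_idx = train_test_split(
        idx,
        test_size=spec.test_fraction,
        stratify=g2_segments.labels,
        random_state=spec.seed,
    )
    result = SplitResult(
        g1_patients=g1,
        g2_patients=g2,
        train=train,
        validation=g2_segments.subset(np.sort(val_idx)),
        test=g2_segments.subset(np.sort(test_idx)),
    )
    result.assert_inter_patient()
    return result


class ConfusionMatrix:
    """2×2 confusion counts over (true, predicted) ∈ {NOR, MI}².

    Counts may be fractional when reconstructed from row-normalized
    published tables.
    """

    def __init__(self, counts: np.ndarray, labels: tuple[str, str] = LABELS):
        counts = np.asarray(counts, dtype=float)
        if counts.shape != (2, 2):
            raise InvalidArgumentError("confusion matrix must be 2x2")
        if (counts < 0).any():
            raise InvalidArgumentError("confusion counts must be nonnegative")
        self.counts = counts
        self.labels = tuple(labels)

    @classmethod
    def from_predictions(cls, y_true, y_pred, labels=LABELS) -> "ConfusionMatrix":
        return cls(_sk_confusion(y_true, y_pred, labels=list(labels)), labels)

    @classmethod
    def from_fractions(cls, row_fractions, class_counts, labels=LABELS) -> "ConfusionMatrix":
        """Rebuild counts from row-normalized fractions and per-class totals."""
        fracs = np.asarray(row_fractions, dtype=float)
        totals = np.asarray(class_counts, dtype=float)
        return cls(fracs * totals[:, None], labels)

    def tp_fp_fn_tn(self, class_index: int) -> tuple[float, float, float, float]:
        c = self.counts
        tp = c[class_index, class_index]
        fp = c[:, class_index].sum() - tp
        fn = c[class_index, :].sum() - tp
        tn = c.sum() - tp - fp - fn
        return tp, fp, fn, tn

    def normalized(self) -> np.ndarray:
        return normalize_confusion(self)


def normalize_confusion(cm: ConfusionMatrix) -> np.ndarray:
    """Row-stochastic form: each row divided by its (positive) sum."""
    sums = cm.counts.sum(axis=1, keepdims=True)
    if (sums == 0).any():
        raise InvalidArgumentError("cannot normalize a confusion matrix with an empty row")
    return cm.counts / sums


@dataclass(frozen=True)
class MetricsRecord:
    """Accuracy plus per-class precision/recall/F1; raw doubles."""

    accuracy: float
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]

    def rounded(self, decimals: int = 2) -> "MetricsRecord":
        return MetricsRecord(
            accuracy=round_half_up(self.accuracy, decimals),
            precision={k: round_half_up(v, decimals) for k, v in self.precision.items()},
            recall={k: round_half_up(v, decimals) for k, v in self.recall.items()},
            f1={k: round_half_up(v, decimals) for k, v in self.f1.items()},
        )

    def as_rows(self) -> list[dict]:
        rows = []
        for label in self.precision:
            rows.append(
                {
                    "class": label,
                    "precision": self.precision[label],
                    "recall": self.recall[label],
                    "f1": self.f1[label],
                    "accuracy": self.accuracy,
                }
            )
        return rows


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        log.warning("undefined %s (zero denominator); reporting 0", what)
        return 0.0
    return num / den


def metrics_from_confusion(cm: ConfusionMatrix) -> MetricsRecord:
    """Per-class precision/recall/F1 and overall accuracy from counts."""
    total = cm.counts.sum()
    if total <= 0:
        raise InvalidArgumentError("confusion matrix has zero total count")
    precision, recall, f1 = {}, {}, {}
    for i, label in enumerate(cm.labels):
        tp, fp, fn, _ = cm.tp_fp_fn_tn(i)
        p = _safe_div(tp, tp + fp, f"precision[{label}]")
        r = _safe_div(tp, tp + fn, f"recall[{label}]")
        precision[label] = p
        recall[label] = r
        f1[label] = _safe_div(2 * p * r, p + r, f"f1[{label}]")
    accuracy = np.trace(cm.counts) / total
    return MetricsRecord(accuracy=float(accuracy), precision=precision,
                         recall=recall, f1=f1)


@dataclass
class RobustnessReport:
    """Metrics over the full {model × noise kind × SNR} grid plus baselines.

    Baseline conditions are keyed with noise kind ``'clean'`` or
    ``'unfiltered'`` and ``snr_db=None``.
    """

    entries: dict[tuple[str, str, float | None], MetricsRecord] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (model, kind, snr), rec in self.entries.items():
            for row in rec.as_rows():
                rows.append({"model": model, "noise": kind, "snr_db": snr, **row})
        return pd.DataFrame(rows)

    def accuracy(self, model: str, kind: str, snr: float | None) -> float:
        return self.entries[(model, kind, snr)].accuracy


def robustness_sweep(
    models: dict[str, object],
    clean_test: SegmentTable,
    noise_kinds=synth.NOISE_KINDS,
    snr_levels_db=noise_mod.SNR_LEVELS_DB,
    *,
    fs: float = 1000.0,
    seed: int = 0,
    unfiltered_test: SegmentTable | None = None,
) -> RobustnessReport:
    """Degradation grid: contaminate the clean test segments and re-predict.

    Models must already be trained (on clean G1 data); they are never
    refit here.  For every (noise kind, SNR) cell one noise realization
    is generated and mixed into each test segment at the exact target
    SNR with seeded window starts.  Clean and (optionally) unfiltered
    baselines are included.
    """
    for name, model in models.items():
        if not hasattr(model, "classes_"):
            raise InvalidStateError(f"model {name!r} is not trained")

    report = RobustnessReport()
    y_true = clean_test.labels

    for name, model in models.items():
        cm = ConfusionMatrix.from_predictions(y_true, predict(model, clean_test.X))
        report.entries[(name, "clean", None)] = metrics_from_confusion(cm)
        if unfiltered_test is not None:
            cm = ConfusionMatrix.from_predictions(
                unfiltered_test.labels, predict(model, unfiltered_test.X)
            )
            report.entries[(name, "unfiltered", None)] = metrics_from_confusion(cm)

    seg_len = clean_test.X.shape[1]
    noise_len_s = max(10.0, 2.0 * seg_len / fs)
    for k, kind in enumerate(noise_kinds):
        trace = synth.generate_noise(
            synth.NoiseSpec(kind=kind, duration_s=noise_len_s,
                            sampling_rate_hz=fs, rng_seed=seed + 1000 * (k + 1))
        )
        for snr in snr_levels_db:
            noisy_X = noise_mod.contaminate_segments(
                clean_test.X, trace, snr, seed=seed + 7919 * (k + 1)
            )
            for name, model in models.items():
                cm = ConfusionMatrix.from_predictions(y_true, predict(model, noisy_X))
                report.entries[(name, kind, float(snr))] = metrics_from_confusion(cm)
    return report
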