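"""Cross-check mode against the published reference tables.

The reference study prints its clean-test and unfiltered-test results
twice: once as per-class metric tables and once as row-normalized
confusion matrices, alongside the G2 segment counts.  This module
reconstructs confusion counts from the normalized rows and the 80%
test share of the G2 counts, and recomputes the metric tables — a
machine check of the published tables' internal consistency.
"""

from __future__ import annotations

import json
from importlib import resources

from .containers import LABELS
from .evaluate import ConfusionMatrix, MetricsRecord, metrics_from_confusion

__all__ = ["load_reference_tables", "reference_confusion", "reference_metrics",
           "recompute_reference_metrics"]

_CACHE: dict | None = None


def load_reference_tables() -> dict:
    """The packaged reference-table fixture (parsed JSON)."""
    global _CACHE
    if _CACHE is None:
        text = resources.files("ecgrobust.data").joinpath("reference_tables.json").read_text()
        _CACHE = json.loads(text)
    return _CACHE


def reference_confusion(condition: str, model: str) -> ConfusionMatrix:
    """Confusion counts for one (condition, model) cell, rebuilt from fractions."""
    tables = load_reference_tables()
    fractions = tables["confusion_row_fractions"][condition][model]
    counts = [tables["test_class_counts"][label] for label in LABELS]
    return ConfusionMatrix.from_fractions(fractions, counts)


def reference_metrics(condition: str, model: str) -> MetricsRecord:
    """The metric cells as printed in the reference tables."""
    rec = load_reference_tables()["reported_metrics"][condition][model]
    return MetricsRecord(
        accuracy=rec["accuracy"],
        precision=dict(rec["precision"]),
        recall=dict(rec["recall"]),
        f1=dict(rec["f1"]),
    )


def recompute_reference_metrics(condition: str, model: str) -> MetricsRecord:
    """Metrics recomputed from the printed confusion fractions (raw doubles)."""
    return metrics_from_confusion(reference_confusion(condition, model))
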