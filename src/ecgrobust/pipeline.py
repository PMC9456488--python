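"""End-to-end orchestration of the two robustness experiments.

``run_pipeline`` chains the stages in the study's order — synthesize a
cohort, preprocess each record (min–max → Butterworth → segment →
detrend), split inter-patient, train the three classifiers on clean G1
segments, and sweep prediction quality over {noise kind × SNR} plus
the clean and unfiltered baselines.

Default problem sizes here are the package's demonstration scale
(small cohorts, few leads, short records) so the full pipeline runs in
minutes on one CPU; every size is a parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import classify, synth
from .containers import SegmentTable
from .evaluate import RobustnessReport, SplitResult, SplitSpec, inter_patient_split
from .noise import SNR_LEVELS_DB
from .preprocess import FilterSpec, NormalizationParams, SegmentationSpec, preprocess_record
from .evaluate import robustness_sweep

__all__ = ["PipelineConfig", "PipelineResult", "build_segment_tables", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Knobs of the end-to-end run; defaults are the demo scale."""

    n_per_class: int = 8
    g1_per_class: int = 5
    n_leads: int = 3
    duration_s: float = 16.0
    fs: float = 1000.0
    seed: int = 0
    families: tuple[str, ...] = classify.FAMILIES
    noise_kinds: tuple[str, ...] = synth.NOISE_KINDS
    snr_levels_db: tuple[float, ...] = SNR_LEVELS_DB
    use_ground_truth_peaks: bool = True
    hyperparameter_overrides: dict = field(default_factory=dict)
    include_unfiltered: bool = True

    @property
    def split_spec(self) -> SplitSpec:
        return SplitSpec(
            g1_patients_per_class=self.g1_per_class,
            g2_patients_per_class=self.n_per_class - self.g1_per_class,
            seed=self.seed,
        )


@dataclass
class PipelineResult:
    split: SplitResult
    models: dict[str, object]
    report: RobustnessReport
    segments: SegmentTable
    segments_unfiltered: SegmentTable | None


def build_segment_tables(
    config: PipelineConfig,
) -> tuple[SegmentTable, SegmentTable | None]:
    """Synthesize the cohort and preprocess every record.

    Returns the filtered segment table and, when requested, the
    row-aligned unfiltered table (same windows, Butterworth skipped).
    """
    cohort = synth.generate_cohort(config.n_per_class, config.seed)
    seg_spec = SegmentationSpec(fs=config.fs)
    norm = NormalizationParams()
    filt = FilterSpec()
    filtered, unfiltered = [], []
    for patient in cohort:
        record, _ = synth.generate_record(
            patient, n_leads=config.n_leads,
            duration_s=config.duration_s, fs=config.fs,
        )
        kwargs = dict(
            norm=norm, seg_spec=seg_spec,
            use_ground_truth_peaks=config.use_ground_truth_peaks,
        )
        filtered.append(preprocess_record(record, filt=filt, apply_filter=True, **kwargs))
        if config.include_unfiltered:
            unfiltered.append(preprocess_record(record, apply_filter=False, **kwargs))
    table = SegmentTable.concat(filtered)
    table_unf = SegmentTable.concat(unfiltered) if config.include_unfiltered else None
    return table, table_unf


def train_models(config: PipelineConfig, train_table: SegmentTable) -> dict[str, object]:
    models = {}
    for family in config.families:
        spec = classify.ModelSpec(
            family,
            dict(config.hyperparameter_overrides.get(family, {})),
            rng_seed=config.seed,
        )
        models[family] = classify.fit(spec, train_table.X, train_table.labels)
    return models


def run_pipeline(config: PipelineConfig | None = None) -> PipelineResult:
    """Execute the full experiment; deterministic given ``config.seed``."""
    config = config or PipelineConfig()
    table, table_unf = build_segment_tables(config)
    split = inter_patient_split(table, config.split_spec)
    split.assert_inter_patient()

    # align the unfiltered table with the same test rows
    unfiltered_test = None
    if table_unf is not None:
        # identical cohort + ground-truth windows => identical row order
        split_unf = inter_patient_split(table_unf, config.split_spec)
        unfiltered_test = split_unf.test

    models = train_models(config, split.train)
    report = robustness_sweep(
        models,
        split.test,
        config.noise_kinds,
        config.snr_levels_db,
        fs=config.fs,
        seed=config.seed,
        unfiltered_test=unfiltered_test,
    )
    return PipelineResult(
        split=split,
        models=models,
        report=report,
        segments=table,
        segments_unfiltered=table_unf,
    )
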