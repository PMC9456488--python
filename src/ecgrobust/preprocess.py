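"""Per-lead ECG preprocessing: normalization, filtering, segmentation.

Stage order is fixed: min–max normalization → low-pass Butterworth →
R-peak detection → beat segmentation → per-segment linear detrending.
Every stage is pure and deterministic.

The low-pass cutoff is expressed as a fraction of the Nyquist
frequency (the standard DSP convention), so the default ``fc = 0.04``
means 20 Hz at a 1000 Hz sampling rate.  An absolute-Hz override is
available through :meth:`FilterSpec.from_hz`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .containers import BeatSegment, ECGRecord, SegmentTable
from .errors import DegenerateSignalError, InvalidArgumentError

__all__ = [
    "NormalizationParams",
    "FilterSpec",
    "SegmentationSpec",
    "normalize_minmax",
    "lowpass_butterworth",
    "detect_r_peaks",
    "segment_beats",
    "detrend_linear",
    "preprocess_record",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class NormalizationParams:
    """Target range [a, b] for min–max scaling; defaults to [0, 1]."""

    a: float = 0.0
    b: float = 1.0

    def __post_init__(self):
        if not self.b > self.a:
            raise InvalidArgumentError("normalization requires b > a")


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth low-pass: order ``order`` and normalized cutoff ``fc``.

    ``fc`` is a fraction of Nyquist, in (0, 1).  ``mode='zero_phase'``
    applies the filter forward and backward (no group delay, magnitude
    response squared); ``mode='causal'`` applies it once.
    """

    order: int = 8
    fc: float = 0.04
    mode: str = "zero_phase"

    def __post_init__(self):
        if self.order < 1:
            raise InvalidArgumentError("filter order must be >= 1")
        if not 0.0 < self.fc < 1.0:
            raise InvalidArgumentError("fc must lie in (0, 1) as a fraction of Nyquist")
        if self.mode not in ("zero_phase", "causal"):
            raise InvalidArgumentError("mode must be 'zero_phase' or 'causal'")

    @classmethod
    def from_hz(cls, cutoff_hz: float, fs: float, order: int = 8,
                mode: str = "zero_phase") -> "FilterSpec":
        return cls(order=order, fc=cutoff_hz / (fs / 2.0), mode=mode)


@dataclass(frozen=True)
class SegmentationSpec:
    """Beat window: ``t1`` seconds before to ``t2`` seconds after the R peak."""

    t1: float = 0.30
    t2: float = 0.35
    fs: float = 1000.0

    def __post_init__(self):
        if self.t1 <= 0 or self.t2 <= 0 or self.fs <= 0:
            raise InvalidArgumentError("t1, t2 and fs must be positive")
        n = (self.t1 + self.t2) * self.fs
        if abs(n - round(n)) > 1e-9:
            raise InvalidArgumentError("(t1 + t2) * fs must be integral")

    @property
    def n_before(self) -> int:
        return int(round(self.t1 * self.fs))

    @property
    def n_after(self) -> int:
        return int(round(self.t2 * self.fs))

    @property
    def n_samples(self) -> int:
        return self.n_before + self.n_after


def normalize_minmax(x: np.ndarray, params: NormalizationParams | None = None) -> np.ndarray:
    """Affine rescaling of ``x`` onto [a, b]:  x' = a + (x - x_min)(b - a)/(x_max - x_min).

    Preserves shape and rank order; raises :class:`DegenerateSignalError`
    for constant input (x_max == x_min).
    """
    params = params or NormalizationParams()
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise InvalidArgumentError("cannot normalize an empty signal")
    x_min, x_max = x.min(), x.max()
    if x_max == x_min:
        raise DegenerateSignalError("constant signal: min–max normalization undefined")
    return params.a + (x - x_min) * (params.b - params.a) / (x_max - x_min)


def lowpass_butterworth(x: np.ndarray, spec: FilterSpec | None = None) -> np.ndarray:
    """Low-pass Butterworth filter with unit DC gain.

    Zero-phase mode squares the magnitude response (−6 dB at fc);
    causal mode gives the textbook −3 dB at fc.
    """
    spec = spec or FilterSpec()
    x = np.asarray(x, dtype=float)
    if x.shape[-1] <= 3 * spec.order:
        raise InvalidArgumentError("signal shorter than filter warm-up (3 * order)")
    sos = sps.butter(spec.order, spec.fc, btype="lowpass", output="sos")
    if spec.mode == "zero_phase":
        return sps.sosfiltfilt(sos, x, axis=-1)
    return sps.sosfilt(sos, x, axis=-1)


def detect_r_peaks(x: np.ndarray, fs: float) -> np.ndarray:
    """QRS detection in the style of Pan–Tompkins.

    Band-pass (5–15 Hz) → derivative → squaring → moving-window
    integration (150 ms) → adaptive-threshold peak picking with a
    200 ms refractory period, then refinement to the local extremum of
    the band-passed signal.  Returns sample indices, strictly
    increasing; an empty array for flat or empty input.
    """
    if fs < 100:
        raise InvalidArgumentError("detect_r_peaks requires fs >= 100 Hz")
    x = np.asarray(x, dtype=float)
    if x.size == 0 or np.ptp(x) == 0:
        return np.array([], dtype=int)

    nyq = fs / 2.0
    sos = sps.butter(2, [5.0 / nyq, 15.0 / nyq], btype="bandpass", output="sos")
    bp = sps.sosfiltfilt(sos, x)
    deriv = np.gradient(bp)
    squared = deriv**2
    win = max(1, int(round(0.150 * fs)))
    mwi = np.convolve(squared, np.ones(win) / win, mode="same")

    refractory = int(round(0.2 * fs))
    threshold = 0.08 * mwi.max()
    cand, _ = sps.find_peaks(mwi, height=threshold, distance=refractory)
    if cand.size == 0:
        return np.array([], dtype=int)

    # refine each candidate to the nearest extremum of |band-passed signal|
    search = int(round(0.06 * fs))
    peaks = []
    for c in cand:
        lo = max(0, c - search)
        hi = min(x.size, c + search + 1)
        peaks.append(lo + int(np.argmax(np.abs(bp[lo:hi]))))
    peaks = np.unique(peaks)
    # enforce refractory after refinement (keep the stronger of close pairs)
    kept: list[int] = []
    for p in peaks:
        if kept and p - kept[-1] < refractory:
            if np.abs(bp[p]) > np.abs(bp[kept[-1]]):
                kept[-1] = int(p)
        else:
            kept.append(int(p))
    return np.asarray(kept, dtype=int)


def segment_beats(
    x: np.ndarray,
    peaks: np.ndarray,
    spec: SegmentationSpec | None = None,
    *,
    lead_id: str = "L0",
    patient_id: str = "",
    class_label: str = "NOR",
) -> list[BeatSegment]:
    """Window ``x`` around each R peak; windows crossing an edge are dropped."""
    spec = spec or SegmentationSpec()
    x = np.asarray(x, dtype=float)
    segments = []
    dropped = 0
    for p in np.asarray(peaks, dtype=int):
        lo = p - spec.n_before
        hi = p + spec.n_after
        if lo < 0 or hi > x.size:
            dropped += 1
            continue
        segments.append(
            BeatSegment(
                samples=x[lo:hi],
                lead_id=lead_id,
                patient_id=patient_id,
                class_label=class_label,
                r_peak_index=int(p),
            )
        )
    if dropped:
        log.info("segment_beats: dropped %d edge beat(s) of %d", dropped, len(peaks))
    return segments


def detrend_linear(seg: np.ndarray) -> np.ndarray:
    """Subtract the least-squares regression line from ``seg``."""
    seg = np.asarray(seg, dtype=float)
    if seg.size < 2:
        raise InvalidArgumentError("detrending requires at least 2 samples")
    return sps.detrend(seg, type="linear")


def preprocess_record(
    record: ECGRecord,
    norm: NormalizationParams | None = None,
    filt: FilterSpec | None = None,
    seg_spec: SegmentationSpec | None = None,
    *,
    apply_filter: bool = True,
    use_ground_truth_peaks: bool = False,
    reference_lead: int = 0,
) -> SegmentTable:
    """Full per-record pipeline producing a detrended segment table.

    R peaks are detected once on ``reference_lead`` (or taken from the
    record's synthetic ground truth) and reused across leads, so each
    lead-beat becomes one classifier sample.  ``apply_filter=False``
    reproduces the unfiltered-test condition of the robustness study.
    """
    seg_spec = seg_spec or SegmentationSpec(fs=record.fs)
    leads = []
    for i in range(record.n_leads):
        lead = normalize_minmax(record.signal[i], norm)
        if apply_filter:
            lead = lowpass_butterworth(lead, filt)
        leads.append(lead)

    if use_ground_truth_peaks:
        if record.r_peaks is None:
            raise InvalidArgumentError("record carries no ground-truth R peaks")
        peaks = np.asarray(record.r_peaks, dtype=int)
    else:
        peaks = detect_r_peaks(leads[reference_lead], record.fs)

    segments = []
    for i, lead in enumerate(leads):
        for seg in segment_beats(
            lead,
            peaks,
            seg_spec,
            lead_id=record.lead_names[i],
            patient_id=record.patient_id,
            class_label=record.label,
        ):
            seg.samples = detrend_linear(seg.samples)
            segments.append(seg)
    return SegmentTable.from_segments(segments)
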