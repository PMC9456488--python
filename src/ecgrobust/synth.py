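"""Synthetic ECG cohorts and noise realizations.

Every downstream stage of the robustness pipeline (preprocessing,
noise injection, quality scoring, classification, evaluation) is
exercisable on records produced here, with no external database.

The beat model is a sum of five Gaussians — one deflection each for
the P, Q, R, S and T waves — repeated at the RR interval with seeded
per-beat timing jitter.  Myocardial-infarction (MI) morphology is
emulated through the three ECG hallmarks of infarction: an ST-segment
baseline offset (elevation or depression), a pathological Q wave
deeper than 25% of the R amplitude, and T-wave inversion.  Each MI
patient expresses a random non-empty subset of the three, so no single
feature trivially separates the classes.

Three noise processes mirror the ambulatory-ECG noise families used in
robustness testing: baseline wander (sub-hertz drift), muscle artifact
(broadband EMG-like noise) and electrode motion artifact (step
transients plus drift).  All realizations are zero-mean and unit
variance before any SNR scaling, and every generator is a pure
function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .containers import ECGRecord, LABELS
from .errors import InvalidArgumentError

__all__ = [
    "BeatTemplate",
    "SyntheticPatient",
    "NoiseSpec",
    "NOISE_KINDS",
    "default_template",
    "generate_record",
    "generate_noise",
    "generate_cohort",
]

#: Recognized noise process names.
NOISE_KINDS = ("baseline_wander", "muscle_artifact", "electrode_motion")

#: ST-measurement window relative to the R peak, seconds.
ST_WINDOW = (0.08, 0.12)

# ST plateau geometry: flat between _ST_FLAT, raised-cosine ramps of
# _ST_RAMP seconds on both sides.  The flat region covers ST_WINDOW so
# the window mean equals st_offset on the reference lead.
_ST_FLAT = (0.06, 0.16)
_ST_RAMP = 0.02


@dataclass(frozen=True)
class BeatTemplate:
    """Sum-of-Gaussians description of one beat.

    ``wave_params`` holds ``(center_s, width_s, amplitude)`` per
    deflection, centers in seconds relative to the R peak, amplitudes
    normalized so the R wave has magnitude ~1.
    """

    wave_params: tuple[tuple[float, float, float], ...]
    st_offset: float = 0.0
    class_label: str = "NOR"

    def __post_init__(self):
        if self.class_label not in LABELS:
            raise InvalidArgumentError(f"class_label must be one of {LABELS}")
        for c, w, a in self.wave_params:
            if w <= 0:
                raise InvalidArgumentError("wave width must be positive")

    @property
    def r_amplitude(self) -> float:
        # R is by convention the largest absolute deflection
        return max(abs(a) for _, _, a in self.wave_params) if self.wave_params else 0.0

    def scaled(self, amp_factors, width_factors) -> "BeatTemplate":
        """Per-wave multiplicative jitter; st_offset is left untouched."""
        waves = tuple(
            (c, w * wf, a * af)
            for (c, w, a), af, wf in zip(self.wave_params, amp_factors, width_factors)
        )
        return replace(self, wave_params=waves)


def default_template(class_label: str = "NOR") -> BeatTemplate:
    """Canonical normal-beat template (P, Q, R, S, T), unit R amplitude."""
    waves = (
        (-0.17, 0.025, 0.15),   # P
        (-0.035, 0.010, -0.08), # Q
        (0.0, 0.012, 1.00),     # R
        (0.035, 0.012, -0.20),  # S
        (0.25, 0.045, 0.35),    # T
    )
    return BeatTemplate(wave_params=waves, st_offset=0.0, class_label=class_label)


@dataclass(frozen=True)
class SyntheticPatient:
    """One simulated subject: identity, class, rhythm and morphology."""

    patient_id: str
    class_label: str
    heart_rate_bpm: float
    template: BeatTemplate
    rr_jitter: float = 0.05   # fractional sd-free uniform RR perturbation
    lead_amp_jitter: float = 0.05
    rng_seed: int = 0

    def __post_init__(self):
        if self.heart_rate_bpm <= 0:
            raise InvalidArgumentError("heart_rate_bpm must be positive")
        if self.class_label not in LABELS:
            raise InvalidArgumentError(f"class_label must be one of {LABELS}")


@dataclass(frozen=True)
class NoiseSpec:
    """Parameters of one noise realization."""

    kind: str
    duration_s: float
    sampling_rate_hz: float
    rng_seed: int = 0

    def __post_init__(self):
        if self.kind not in NOISE_KINDS:
            raise InvalidArgumentError(
                f"unknown noise kind {self.kind!r}; expected one of {NOISE_KINDS}"
            )
        if self.duration_s <= 0 or self.sampling_rate_hz <= 0:
            raise InvalidArgumentError("duration_s and sampling_rate_hz must be positive")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.sampling_rate_hz))


# ----------------------------------------------------------------------
# record generation
# ----------------------------------------------------------------------

def _st_plateau(t: np.ndarray) -> np.ndarray:
    """Unit-height ST plateau with raised-cosine edges, t relative to R."""
    lo, hi = _ST_FLAT
    ramp = _ST_RAMP
    y = np.zeros_like(t)
    flat = (t >= lo) & (t <= hi)
    y[flat] = 1.0
    rise = (t >= lo - ramp) & (t < lo)
    y[rise] = 0.5 * (1 - np.cos(np.pi * (t[rise] - (lo - ramp)) / ramp))
    fall = (t > hi) & (t <= hi + ramp)
    y[fall] = 0.5 * (1 + np.cos(np.pi * (t[fall] - hi) / ramp))
    return y


def _beat_waveform(t: np.ndarray, template: BeatTemplate) -> np.ndarray:
    """Evaluate one beat on time axis ``t`` (seconds relative to R)."""
    y = np.zeros_like(t)
    for c, w, a in template.wave_params:
        if a != 0.0:
            y += a * np.exp(-0.5 * ((t - c) / w) ** 2)
    if template.st_offset != 0.0:
        y += template.st_offset * _st_plateau(t)
    return y


def _schedule_r_peaks(
    heart_rate_bpm: float, duration_s: float, fs: float, rr_jitter: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """R-peak sample indices: first beat at RR/2, then jittered RR steps."""
    rr = 60.0 / heart_rate_bpm
    times = []
    t = 0.5 * rr
    while t < duration_s:
        times.append(t)
        step = rr * (1.0 + (rng.uniform(-rr_jitter, rr_jitter) if rr_jitter > 0 else 0.0))
        t += step
    idx = np.round(np.asarray(times) * fs).astype(int)
    return idx[idx < int(round(duration_s * fs))]


def generate_record(
    patient: SyntheticPatient,
    n_leads: int = 12,
    duration_s: float = 32.0,
    fs: float = 1000.0,
) -> tuple[ECGRecord, np.ndarray]:
    """Simulate one multi-lead record for ``patient``.

    Each lead is an amplitude-scaled (occasionally sign-flipped) variant
    of the patient's beat template with independent per-lead, per-wave
    amplitude jitter; lead 0 is the unscaled reference lead.  Returns
    the record together with the ground-truth R-peak sample indices.
    Deterministic given the patient's seed.
    """
    if duration_s <= 0 or fs <= 0:
        raise InvalidArgumentError("duration_s and fs must be positive")
    if n_leads < 1:
        raise InvalidArgumentError("n_leads must be >= 1")
    rr = 60.0 / patient.heart_rate_bpm
    if duration_s < rr:
        raise InvalidArgumentError(
            f"duration {duration_s}s holds no beat at {patient.heart_rate_bpm} bpm"
        )

    rng = np.random.default_rng(patient.rng_seed)
    peaks = _schedule_r_peaks(patient.heart_rate_bpm, duration_s, fs, patient.rr_jitter, rng)
    n_samples = int(round(duration_s * fs))
    n_waves = len(patient.template.wave_params)

    # support of one beat around R, generous enough for P and T tails
    half = 0.45
    w = int(round(half * fs))
    t_local = np.arange(-w, w + 1) / fs

    signal = np.zeros((n_leads, n_samples))
    for lead in range(n_leads):
        if lead == 0:
            scale = 1.0
        else:
            scale = rng.uniform(0.6, 1.1) * (-1.0 if rng.uniform() < 0.25 else 1.0)
        for p in peaks:
            amp_f = 1.0 + patient.lead_amp_jitter * rng.standard_normal(n_waves)
            beat = _beat_waveform(t_local, patient.template.scaled(amp_f, np.ones(n_waves)))
            lo = max(0, p - w)
            hi = min(n_samples, p + w + 1)
            signal[lead, lo:hi] += scale * beat[(lo - p + w):(hi - p + w)]

    record = ECGRecord(
        signal=signal,
        fs=fs,
        patient_id=patient.patient_id,
        label=patient.class_label,
        r_peaks=peaks,
    )
    return record, peaks


# ----------------------------------------------------------------------
# noise generation
# ----------------------------------------------------------------------

def _standardize(x: np.ndarray) -> np.ndarray:
    x = x - x.mean()
    sd = x.std()
    if sd == 0:
        raise InvalidArgumentError("degenerate noise realization with zero variance")
    return x / sd


def _baseline_wander(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    t = np.arange(n) / fs
    y = np.zeros(n)
    for _ in range(6):
        f = rng.uniform(0.05, 0.45)
        a = rng.uniform(0.5, 1.0)
        phi = rng.uniform(0, 2 * np.pi)
        y += a * np.sin(2 * np.pi * f * t + phi)
    return y


def _muscle_artifact(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    white = rng.standard_normal(n)
    nyq = fs / 2.0
    lo = min(20.0, 0.2 * nyq)
    hi = min(200.0, 0.9 * nyq)
    sos = sps.butter(4, [lo / nyq, hi / nyq], btype="bandpass", output="sos")
    return sps.sosfiltfilt(sos, white)


def _electrode_motion(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    duration = n / fs
    n_steps = max(1, rng.poisson(0.5 * duration))
    step_idx = rng.integers(0, n, size=n_steps)
    step_amp = rng.laplace(0.0, 1.0, size=n_steps)
    steps = np.zeros(n)
    for i, a in zip(step_idx, step_amp):
        steps[i:] += a
    # soften step edges to ~50 ms transients
    edge = max(3, int(round(0.05 * fs)))
    kernel = np.hanning(edge)
    kernel /= kernel.sum()
    steps = np.convolve(steps, kernel, mode="same")
    t = np.arange(n) / fs
    drift = 0.5 * np.sin(2 * np.pi * rng.uniform(0.05, 0.3) * t + rng.uniform(0, 2 * np.pi))
    return steps + drift


_NOISE_FUNCS = {
    "baseline_wander": _baseline_wander,
    "muscle_artifact": _muscle_artifact,
    "electrode_motion": _electrode_motion,
}


def generate_noise(spec: NoiseSpec) -> np.ndarray:
    """One zero-mean, unit-variance noise realization of ``spec.kind``."""
    rng = np.random.default_rng(spec.rng_seed)
    raw = _NOISE_FUNCS[spec.kind](spec.n_samples, spec.sampling_rate_hz, rng)
    return _standardize(raw)


# ----------------------------------------------------------------------
# cohort generation
# ----------------------------------------------------------------------

def _mi_template(base: BeatTemplate, rng: np.random.Generator) -> BeatTemplate:
    """Apply a random non-empty subset of the three MI hallmarks."""
    hallmarks = ["st", "q", "t"]
    chosen = [h for h in hallmarks if rng.uniform() < 0.6]
    if not chosen:
        chosen = [hallmarks[rng.integers(0, 3)]]
    waves = [list(wv) for wv in base.wave_params]
    st = 0.0
    if "st" in chosen:
        st = rng.choice([-1.0, 1.0]) * rng.uniform(0.15, 0.30)
    if "q" in chosen:  # pathological Q: deeper than 25% of R
        waves[1][2] = -rng.uniform(0.30, 0.50) * abs(waves[2][2])
    if "t" in chosen:  # T inversion
        waves[4][2] = -abs(waves[4][2]) * rng.uniform(0.8, 1.2)
    return BeatTemplate(
        wave_params=tuple(tuple(wv) for wv in waves),
        st_offset=st,
        class_label="MI",
    )


def generate_cohort(n_per_class: int, seed: int) -> list[SyntheticPatient]:
    """A balanced cohort of ``2 * n_per_class`` patients.

    Per-patient seeds, heart rates and morphology jitter are all derived
    deterministically from the master seed; identical seeds reproduce
    the cohort bit-for-bit.
    """
    if n_per_class < 1:
        raise InvalidArgumentError("n_per_class must be >= 1")
    master = np.random.default_rng(np.random.SeedSequence(seed))
    patients: list[SyntheticPatient] = []
    for label in LABELS:
        for i in range(n_per_class):
            rng = np.random.default_rng(master.integers(0, 2**31))
            base = default_template(label)
            n_waves = len(base.wave_params)
            amp_f = 1.0 + 0.10 * rng.standard_normal(n_waves)
            width_f = np.clip(1.0 + 0.10 * rng.standard_normal(n_waves), 0.5, 1.5)
            template = base.scaled(amp_f, width_f)
            if label == "MI":
                template = _mi_template(template, rng)
            patients.append(
                SyntheticPatient(
                    patient_id=f"{label}{i + 1:03d}",
                    class_label=label,
                    heart_rate_bpm=float(rng.uniform(60.0, 90.0)),
                    template=template,
                    rr_jitter=0.05,
                    rng_seed=int(rng.integers(0, 2**31)),
                )
            )
    return patients
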