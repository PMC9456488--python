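"""SNR-calibrated noise injection.

A noise trace is scaled so that the resulting signal-to-noise ratio,
SNR = 10·log10(P_signal / P_noise) with P the mean squared amplitude,
hits the requested decibel target exactly.  The canonical severity
ladder of the robustness protocol is {16, 8, 2, −2} dB, best to worst.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .errors import DegenerateSignalError, InvalidArgumentError

__all__ = ["SNR_LEVELS_DB", "mix_at_snr", "measured_snr_db", "contaminate_segments"]

#: Canonical SNR ladder, best to worst quality (dB).
SNR_LEVELS_DB = (16.0, 8.0, 2.0, -2.0)


def _power(x: np.ndarray) -> float:
    return float(np.mean(np.square(x)))


def measured_snr_db(clean: np.ndarray, scaled_noise: np.ndarray) -> float:
    """10·log10(P_clean / P_noise) of an already-mixed pair."""
    return 10.0 * np.log10(_power(clean) / _power(scaled_noise))


def mix_at_snr(
    clean: np.ndarray,
    noise: np.ndarray,
    snr_db: float,
    *,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, float]:
    """Add ``noise`` to ``clean`` at exactly ``snr_db`` decibels.

    The noise trace must be at least as long as the signal; a window of
    matching length is cut at a seeded start position (start 0 when no
    ``rng`` is given), mean-removed, and scaled by
    ``k = sqrt(P_clean / (P_noise · 10^(snr/10)))``.

    Returns ``(contaminated, k)``.
    """
    if not np.isfinite(snr_db):
        raise InvalidArgumentError("snr_db must be finite")
    clean = np.asarray(clean, dtype=float)
    noise = np.asarray(noise, dtype=float)
    if noise.size < clean.size:
        raise InvalidArgumentError("noise must be at least as long as the clean signal")
    p_clean = _power(clean)
    if p_clean == 0.0:
        raise DegenerateSignalError("zero-power signal: SNR undefined")

    if noise.size > clean.size:
        max_start = noise.size - clean.size
        start = int(rng.integers(0, max_start + 1)) if rng is not None else 0
        window = noise[start:start + clean.size]
    else:
        window = noise
    window = window - window.mean()
    p_noise = _power(window)
    if p_noise == 0.0:
        raise InvalidArgumentError("zero-power noise window")

    k = float(np.sqrt(p_clean / (p_noise * 10.0 ** (snr_db / 10.0))))
    return clean + k * window, k


def contaminate_segments(
    X: np.ndarray,
    noise_trace: np.ndarray,
    snr_db: float,
    *,
    seed: int = 0,
) -> np.ndarray:
    """Mix a noise realization into every row of a segment matrix.

    Each row receives an independent, seeded window of ``noise_trace``
    scaled to the exact per-row SNR target.
    """
    X = np.asarray(X, dtype=float)
    rng = np.random.default_rng(seed)
    out = np.empty_like(X)
    for i in range(X.shape[0]):
        out[i], _ = mix_at_snr(X[i], noise_trace, snr_db, rng=rng)
    return out
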