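"""Signal-quality measures: MSE, approximate entropy, fuzzy entropy.

Both entropies quantify the (ir)regularity of a series by comparing
how often m-length embedded templates match within a tolerance r
against how often the corresponding (m+1)-length templates do.  A
noisier, less predictable trace scores higher.  Approximate entropy
(ApEn) uses a hard match threshold and includes self-matches; fuzzy
entropy (FzEn) replaces the threshold with an exponential membership
``exp(-d^n / r)`` of the template distance, removes each template's
own baseline (mean), and excludes self-matches.

Conventions (configurable via :class:`EntropyParams`):

* distance — Chebyshev (the canonical choice for both statistics);
  Euclidean available as an option,
* tolerance — ``r`` is a fraction of the series' standard deviation
  by default (``r_mode='sd_relative'``), making both measures
  invariant under affine amplitude changes; absolute mode available,
* FzEn normalization — 1/(N−m) over templates and 1/(N−m−1) over
  match partners, the standard fuzzy-entropy normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import InsufficientLengthError, InvalidArgumentError

__all__ = ["EntropyParams", "mse", "approximate_entropy", "fuzzy_entropy",
           "quality_table"]


@dataclass(frozen=True)
class EntropyParams:
    """Embedding dimension m, tolerance r, fuzzy exponent n."""

    m: int = 2
    r: float = 0.2
    n: float = 2.0
    r_mode: str = "sd_relative"
    metric: str = "chebyshev"

    def __post_init__(self):
        if self.m < 1:
            raise InvalidArgumentError("embedding dimension m must be >= 1")
        if self.r <= 0:
            raise InvalidArgumentError("tolerance r must be positive")
        if self.n <= 0:
            raise InvalidArgumentError("fuzzy exponent n must be positive")
        if self.r_mode not in ("sd_relative", "absolute"):
            raise InvalidArgumentError("r_mode must be 'sd_relative' or 'absolute'")
        if self.metric not in ("chebyshev", "euclidean"):
            raise InvalidArgumentError("metric must be 'chebyshev' or 'euclidean'")

    def effective_r(self, x: np.ndarray) -> float:
        if self.r_mode == "absolute":
            return self.r
        sd = float(np.std(x))
        # constant series: any positive tolerance gives the same (zero) entropy
        return self.r * sd if sd > 0 else self.r


def mse(original: np.ndarray, processed: np.ndarray) -> float:
    """Mean squared error (1/L)·Σ (original − processed)² between two traces."""
    original = np.asarray(original, dtype=float)
    processed = np.asarray(processed, dtype=float)
    if original.shape != processed.shape:
        raise InvalidArgumentError("mse requires equal-length signals")
    if original.size == 0:
        raise InvalidArgumentError("mse requires at least one sample")
    return float(np.mean((original - processed) ** 2))


def _embed(x: np.ndarray, m: int, count: int) -> np.ndarray:
    """First ``count`` overlapping m-length templates of ``x``."""
    return np.lib.stride_tricks.sliding_window_view(x, m)[:count]


def approximate_entropy(x: np.ndarray, params: EntropyParams | None = None) -> float:
    """Approximate entropy ApEn(m, r) = Φ_m(r) − Φ_{m+1}(r).

    Φ_m is the mean over templates i of ln C_i^m(r), where C_i^m is the
    fraction of templates j (self-match included) within distance r.
    """
    params = params or EntropyParams()
    x = np.asarray(x, dtype=float)
    N = x.size
    if N <= params.m + 1:
        raise InsufficientLengthError(f"need N > m + 1 = {params.m + 1}, got N = {N}")
    r_eff = params.effective_r(x)

    def phi(m: int) -> float:
        templates = _embed(x, m, N - m + 1)
        d = cdist(templates, templates, metric=params.metric)
        C = (d <= r_eff).sum(axis=1) / (N - m + 1)
        return float(np.mean(np.log(C)))

    return phi(params.m) - phi(params.m + 1)


def fuzzy_entropy(x: np.ndarray, params: EntropyParams | None = None) -> float:
    """Fuzzy entropy FzEn(m, n, r) = ln Φ_m(n, r) − ln Φ_{m+1}(n, r).

    Templates are baseline-removed (own mean subtracted); similarity is
    ``D_ij = exp(-d_ij^n / r)``; Φ averages D over all ordered pairs
    with j ≠ i.
    """
    params = params or EntropyParams()
    x = np.asarray(x, dtype=float)
    N = x.size
    if N <= params.m + 1:
        raise InsufficientLengthError(f"need N > m + 1 = {params.m + 1}, got N = {N}")
    r_eff = params.effective_r(x)

    def phi(m: int) -> float:
        count = N - params.m  # same template count at both orders
        templates = _embed(x, m, count)
        templates = templates - templates.mean(axis=1, keepdims=True)
        d = cdist(templates, templates, metric=params.metric)
        D = np.exp(-(d**params.n) / r_eff)
        np.fill_diagonal(D, 0.0)
        return float(D.sum() / (count * (count - 1)))

    return float(np.log(phi(params.m)) - np.log(phi(params.m + 1)))


def quality_table(
    clean_X: np.ndarray,
    noisy_X: np.ndarray,
    labels: np.ndarray,
    params: EntropyParams | None = None,
) -> pd.DataFrame:
    """Per-class mean MSE / ApEn / FzEn of contaminated segments.

    ``clean_X`` and ``noisy_X`` are aligned segment matrices; entropy is
    computed per segment on the contaminated trace, MSE against clean.
    """
    params = params or EntropyParams()
    labels = np.asarray(labels)
    rows = []
    for label in np.unique(labels):
        idx = np.flatnonzero(labels == label)
        rows.append(
            {
                "class": str(label),
                "mse": float(np.mean([mse(clean_X[i], noisy_X[i]) for i in idx])),
                "apen": float(np.mean([approximate_entropy(noisy_X[i], params) for i in idx])),
                "fzen": float(np.mean([fuzzy_entropy(noisy_X[i], params) for i in idx])),
                "n_segments": int(idx.size),
            }
        )
    return pd.DataFrame(rows)
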