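"""Morgera's covariance complexity and index of synchrony.

Let Gamma be a P x N matrix holding one neuron's activity time series
per column (P samples, N neurons, P >> N for validity).  The singular
values lambda_i of the column-centered matrix give variance fractions

    sigma_i = lambda_i^2 / sum_j lambda_j^2,

and the covariance complexity is the normalized spectral entropy

    C = -(1 / log N) * sum_k sigma_k log sigma_k,

with 0 log 0 = 0.  The index of synchrony is M = 1 - C: it is 1 when a
single component carries all variance (every neuron a copy of one
waveform) and tends to 0 when all components contribute equally
(independent activity).  C is base-invariant thanks to the 1/log N
normalization; M is invariant to column permutation and to global
rescaling of the matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import svdvals

__all__ = [
    "RasterMatrix",
    "covariance_complexity",
    "morgera_index",
    "synchrony_report",
]


@dataclass
class RasterMatrix:
    """P x N activity matrix (samples by neurons) with its sample period."""

    values: np.ndarray
    sample_period_ms: float = 1.0
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster matrix must be two-dimensional")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.values.shape[1]


def _variance_fractions(
    gamma: RasterMatrix | np.ndarray,
    drop_silent: bool = True,
    min_ratio: float = 10.0,
    normalize: str = "center",
) -> tuple[np.ndarray, int]:
    values = gamma.values if isinstance(gamma, RasterMatrix) else np.asarray(gamma, float)
    if values.ndim != 2:
        raise ValueError("input must be a 2-D samples-by-neurons matrix")
    P, N = values.shape
    centered = values - values.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(centered, axis=0)
    dropped = 0
    if drop_silent:
        # relative threshold so constant columns that center to rounding
        # dust (rather than exact zero) are still treated as silent
        scale = np.abs(values).max(axis=0)
        keep = norms > 1e-10 * np.sqrt(P) * scale
        dropped = int(N - keep.sum())
        centered = centered[:, keep]
        norms = norms[keep]
    if normalize == "zscore":
        centered = centered / np.where(norms > 0, norms, 1.0)
    elif normalize != "center":
        raise ValueError(f"unknown normalize mode {normalize!r}")
    N_eff = centered.shape[1]
    if N_eff < 2:
        raise ValueError(
            "need at least 2 non-constant columns after centering "
            f"(got {N_eff}; {dropped} silent columns dropped)"
        )
    if P < N_eff:
        raise ValueError(f"need at least as many samples as neurons (P={P}, N={N_eff})")
    if P < min_ratio * N_eff:
        warnings.warn(
            f"samples/neurons ratio {P / N_eff:.1f} below {min_ratio}; "
            "the complexity estimate may be biased",
            stacklevel=3,
        )
    lam = svdvals(centered)
    total = float(np.sum(lam**2))
    if total == 0.0:
        raise ValueError("matrix is identically zero after centering")
    return lam**2 / total, dropped


def covariance_complexity(
    gamma: RasterMatrix | np.ndarray,
    drop_silent: bool = True,
    min_ratio: float = 10.0,
    normalize: str = "center",
) -> float:
    """Normalized spectral entropy C in [0, 1] of the centered matrix.

    normalize="center" subtracts each column mean (covariance spectrum,
    the default); normalize="zscore" additionally rescales each column
    to unit variance (correlation spectrum), so that strongly and weakly
    active neurons weigh equally in the synchrony estimate.
    """
    sigma, _ = _variance_fractions(gamma, drop_silent, min_ratio, normalize)
    nz = sigma[sigma > 0]
    C = float(-(nz * np.log(nz)).sum() / np.log(sigma.size))
    return min(max(C, 0.0), 1.0)


def morgera_index(
    gamma: RasterMatrix | np.ndarray,
    drop_silent: bool = True,
    min_ratio: float = 10.0,
    normalize: str = "center",
) -> float:
    """Index of synchrony M = 1 - C: 1 fully synchronized, -> 0 random."""
    return 1.0 - covariance_complexity(gamma, drop_silent, min_ratio, normalize)


def synchrony_report(
    gamma: RasterMatrix | np.ndarray,
    drop_silent: bool = True,
    min_ratio: float = 10.0,
    normalize: str = "center",
) -> dict:
    """M, C, matrix shape and dropped-column count as a JSON-ready dict."""
    sigma, dropped = _variance_fractions(gamma, drop_silent, min_ratio, normalize)
    nz = sigma[sigma > 0]
    C = float(-(nz * np.log(nz)).sum() / np.log(sigma.size))
    C = min(max(C, 0.0), 1.0)
    values = gamma.values if isinstance(gamma, RasterMatrix) else np.asarray(gamma)
    return {
        "M": 1.0 - C,
        "C": C,
        "n_samples": int(values.shape[0]),
        "n_neurons": int(sigma.size),
        "dropped_columns": dropped,
    }
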