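"""LFP estimation and spectral analysis.

The cortical local field potential is approximated as a point-source
superposition of postsynaptic currents: the sum of excitatory PSCs over
the deep cortical layer (D) plus inhibitory PSCs over the cortical
interneuron pool (CI), scaled by 1 / (4 pi sigma r) with sigma the gray
matter conductivity and r the electrode-to-neuron distance.

Spectral quantities: Welch power spectral density, band power by
trapezoidal integration (default band: beta, 13-30 Hz), attenuation as
the off-minus-on band-power difference (positive = suppression), and a
harmonic-comb detector used to find stimulation-locked peaks (e.g. the
20/40/60 Hz comb under 20 Hz periodic stimulation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sig

__all__ = [
    "LFPConfig",
    "PSDResult",
    "estimate_lfp",
    "compute_psd",
    "band_power",
    "beta_attenuation",
    "find_harmonic_comb",
    "BETA_BAND",
]

BETA_BAND = (13.0, 30.0)


@dataclass(frozen=True)
class LFPConfig:
    """Gray-matter conductivity sigma (S/m) and electrode distance r (m)."""

    sigma: float = 0.27
    r: float = 1e-4

    def __post_init__(self) -> None:
        if not self.sigma > 0 or not self.r > 0:
            raise ValueError("sigma and r must be positive")

    @property
    def scale(self) -> float:
        return 1.0 / (4.0 * np.pi * self.sigma * self.r)


@dataclass(frozen=True)
class PSDResult:
    """Frequency grid (Hz), power density values and estimator metadata."""

    freqs: np.ndarray
    power: np.ndarray
    fs: float
    window_s: float
    overlap: float

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.power) < 0):
            raise ValueError("power density must be non-negative")


def estimate_lfp(result, config: LFPConfig | None = None) -> np.ndarray:
    """LFP(t) = [sum of D-layer EPSC + sum of CI-layer IPSC] / (4 pi sigma r).

    ``result`` is a SimulationResult (or any object exposing
    ``psc_exc``/``psc_inh`` arrays of shape (n_populations, n_steps) and a
    ``population_index`` mapping).
    """
    config = config or LFPConfig()
    try:
        d = result.population_index["D"]
        ci = result.population_index["CI"]
        epsc = result.psc_exc[d]
        ipsc = result.psc_inh[ci]
    except (AttributeError, KeyError, IndexError) as exc:
        raise ValueError("result lacks D-layer EPSC / CI-layer IPSC traces") from exc
    return config.scale * (epsc + ipsc)


def compute_psd(
    x: np.ndarray,
    fs: float,
    window_s: float = 1.0,
    overlap: float = 0.5,
) -> PSDResult:
    """Welch PSD with Hann windows of ``window_s`` seconds and fractional
    ``overlap``; units are (signal units)^2 / Hz."""
    x = np.asarray(x, dtype=float)
    nperseg = int(round(window_s * fs))
    if x.size < nperseg:
        raise ValueError(
            f"signal ({x.size} samples) shorter than the window ({nperseg} samples)"
        )
    if not 0.0 <= overlap < 1.0:
        raise ValueError("overlap fraction must lie in [0, 1)")
    f, p = _sig.welch(
        x, fs=fs, window="hann", nperseg=nperseg,
        noverlap=int(round(overlap * nperseg)), detrend="constant",
    )
    return PSDResult(f, p, fs, window_s, overlap)


def band_power(psd: PSDResult, low: float = BETA_BAND[0], high: float = BETA_BAND[1]) -> float:
    """Trapezoidal integral of the PSD over [low, high] Hz."""
    if not low < high:
        raise ValueError(f"inverted band [{low}, {high}]")
    if low < psd.freqs[0] - 1e-9 or high > psd.freqs[-1] + 1e-9:
        raise ValueError("band outside the frequency grid")
    grid = np.unique(np.concatenate([[low], psd.freqs[(psd.freqs > low) & (psd.freqs < high)], [high]]))
    vals = np.interp(grid, psd.freqs, psd.power)
    return float(np.trapezoid(vals, grid))


def beta_attenuation(
    psd_off: PSDResult,
    psd_on: PSDResult,
    low: float = BETA_BAND[0],
    high: float = BETA_BAND[1],
) -> float:
    """Off-period minus on-period band power; positive means suppression."""
    if psd_off.freqs.shape != psd_on.freqs.shape or not np.allclose(
        psd_off.freqs, psd_on.freqs
    ):
        raise ValueError("off/on PSDs are on different frequency grids")
    return band_power(psd_off, low, high) - band_power(psd_on, low, high)


def find_harmonic_comb(
    psd: PSDResult,
    fundamental: float,
    n_harmonics: int,
    tolerance: float = 2.0,
) -> list[dict]:
    """Look for local PSD maxima at k * fundamental, k = 1..n_harmonics.

    For each harmonic, reports whether a local maximum of the PSD lies
    within ``tolerance`` Hz and its prominence (peak power over the
    median power in a +-3*tolerance neighbourhood).
    """
    if n_harmonics * fundamental >= psd.fs / 2:
        raise ValueError("harmonic band extends beyond Nyquist")
    peaks, props = _sig.find_peaks(psd.power)
    peak_freqs = psd.freqs[peaks]
    report = []
    for k in range(1, n_harmonics + 1):
        target = k * fundamental
        found = False
        freq = float("nan")
        prominence = float("nan")
        if peak_freqs.size:
            i = int(np.argmin(np.abs(peak_freqs - target)))
            if abs(peak_freqs[i] - target) <= tolerance:
                found = True
                freq = float(peak_freqs[i])
                lo, hi = target - 3 * tolerance, target + 3 * tolerance
                nb = psd.power[(psd.freqs >= lo) & (psd.freqs <= hi)]
                base = float(np.median(nb)) if nb.size else 0.0
                prominence = float(psd.power[peaks[i]] / base) if base > 0 else float("inf")
        report.append(
            {"harmonic": k, "target_hz": target, "detected": found,
             "peak_hz": freq, "prominence": prominence}
        )
    return report
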