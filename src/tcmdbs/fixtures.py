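"""Controlled synthetic rasters and signals with known structure.

These generators exercise the analysis metrics (synchrony index, PSD,
band power, harmonic detection) independently of the network simulator:
a fully synchronized raster must score M = 1, independent Poisson
trains must score near 0, and tone mixtures place spectral peaks at
known frequencies.  Fixtures never import the simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .synchrony import RasterMatrix

__all__ = ["FixtureSpec", "make_raster", "make_signal"]

RASTER_KINDS = ("synchronized", "jittered", "independent_poisson")


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a synthetic raster or signal.

    kind: one of synchronized | jittered | independent_poisson for
    rasters, tone_mixture for signals.  ``rate_hz`` is the master spike
    rate (rasters) or the tone frequencies (signals, with matching
    ``amplitudes``); ``jitter_sd_ms`` spreads each neuron's copy of the
    master train in time; ``noise_sd`` adds white noise to signals.
    """

    kind: str
    n_neurons: int = 2
    n_samples: int = 1000
    sample_period_ms: float = 1.0
    rate_hz: "float | tuple[float, ...]" = 10.0
    amplitudes: "float | tuple[float, ...]" = 1.0
    jitter_sd_ms: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_neurons < 2:
            raise ValueError("need at least 2 neurons")
        if self.n_samples < self.n_neurons:
            raise ValueError("need at least as many samples as neurons")


def _master_train(rng: np.random.Generator, spec: FixtureSpec) -> np.ndarray:
    """Homogeneous Poisson spike times (ms) over the raster duration."""
    rate = float(spec.rate_hz)
    if rate <= 0:
        raise ValueError(f"rate must be positive, got {spec.rate_hz}")
    duration_ms = spec.n_samples * spec.sample_period_ms
    n_exp = rate * duration_ms / 1000.0
    n = rng.poisson(n_exp)
    return np.sort(rng.uniform(0.0, duration_ms, size=n))


def _bin_times(times: np.ndarray, spec: FixtureSpec) -> np.ndarray:
    col = np.zeros(spec.n_samples)
    idx = np.floor(times / spec.sample_period_ms).astype(int)
    idx = idx[(idx >= 0) & (idx < spec.n_samples)]
    col[np.unique(idx)] = 1.0
    return col


def make_raster(spec: FixtureSpec) -> RasterMatrix:
    """Binary P x N raster with the requested synchrony structure.

    synchronized: one master train copied to every column; jittered: the
    master train with per-neuron, per-spike Gaussian time jitter;
    independent_poisson: independent homogeneous trains per column.
    """
    if spec.kind not in RASTER_KINDS:
        raise ValueError(f"unknown raster kind {spec.kind!r}; known: {RASTER_KINDS}")
    rng = np.random.default_rng(spec.seed)
    cols = np.empty((spec.n_samples, spec.n_neurons))
    if spec.kind == "synchronized":
        col = _bin_times(_master_train(rng, spec), spec)
        if col.sum() == 0:
            raise ValueError("master train empty; raise rate or duration")
        cols[:] = col[:, None]
    elif spec.kind == "jittered":
        master = _master_train(rng, spec)
        for j in range(spec.n_neurons):
            jit = master + rng.normal(0.0, spec.jitter_sd_ms, size=master.size)
            cols[:, j] = _bin_times(jit, spec)
    else:
        for j in range(spec.n_neurons):
            cols[:, j] = _bin_times(_master_train(rng, spec), spec)
    return RasterMatrix(cols, spec.sample_period_ms)


def make_signal(spec: FixtureSpec) -> tuple[np.ndarray, float]:
    """Tone mixture plus optional white noise; returns (signal, fs_hz).

    ``rate_hz`` holds the tone frequencies and ``amplitudes`` their peak
    amplitudes (scalars broadcast).  Frequencies must stay below the
    Nyquist rate implied by the sample period.
    """
    if spec.kind != "tone_mixture":
        raise ValueError("make_signal requires kind='tone_mixture'")
    fs = 1000.0 / spec.sample_period_ms
    freqs = np.atleast_1d(np.asarray(spec.rate_hz, dtype=float))
    amps = np.broadcast_to(
        np.atleast_1d(np.asarray(spec.amplitudes, dtype=float)), freqs.shape
    )
    if np.any(freqs >= fs / 2):
        raise ValueError(f"tone frequency at or above Nyquist ({fs / 2} Hz)")
    t = np.arange(spec.n_samples) / fs
    sig = np.zeros(spec.n_samples)
    for f, a in zip(freqs, amps):
        sig += a * np.sin(2 * np.pi * f * t)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        sig = sig + rng.normal(0.0, spec.noise_sd, size=spec.n_samples)
    return sig, fs
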