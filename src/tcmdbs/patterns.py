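"""Stimulation pulse-train generators.

All protocols are represented by one type, :class:`PulseTrain`: an
ordered list of Dirac event times with a common amplitude.  Generation
is grid-free; discretization onto the simulation grid happens only in
:func:`inject`, which realizes each Dirac event as a one-step
rectangular current of height amplitude/dt so its time-integral equals
the Dirac weight.

Protocols:

* ``cdbs``  — conventional DBS: periodic pulses at f_dbs from onset to
  the end of the window.
* ``a_dbs`` — an onset burst of 20 pulses at 130 Hz followed by tonic
  pulsing at 95 Hz.
* ``b_dbs`` — the same 20-pulse onset burst followed by repeating packs
  of 4 pulses at 130 Hz separated by 37 ms pauses (pack repetition rate
  about 16.6 per second).

Event windows are half-open, [onset, total_time).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "PulseTrain",
    "cdbs",
    "a_dbs",
    "b_dbs",
    "scale_amplitude",
    "select_targets",
    "inject",
]

BURST_PULSES = 20
BURST_HZ = 130.0
ADBS_TONIC_HZ = 95.0
BDBS_PACK_PULSES = 4
BDBS_PAUSE_S = 0.037


@dataclass(frozen=True)
class PulseTrain:
    """Ordered stimulus events (s) with a common pulse amplitude."""

    event_times: np.ndarray
    amplitude: float
    onset: float
    total_time: float

    def __post_init__(self) -> None:
        t = np.asarray(self.event_times, dtype=float)
        object.__setattr__(self, "event_times", t)
        if t.size:
            if not np.all(np.diff(t) > 0):
                raise ValueError("event times must be strictly increasing")
            if t[0] < self.onset - 1e-12 or t[-1] >= self.total_time:
                raise ValueError("event times must lie in [onset, total_time)")

    def __len__(self) -> int:
        return int(self.event_times.size)

    def to_csv(self, path) -> None:
        """Two-column CSV export (time_s, amplitude)."""
        arr = np.column_stack(
            [self.event_times, np.full(len(self), self.amplitude)]
        )
        np.savetxt(path, arr, delimiter=",", header="time_s,amplitude", comments="")


def _empty(onset: float, total_time: float, amplitude: float) -> PulseTrain:
    return PulseTrain(np.empty(0), amplitude, onset, total_time)


def cdbs(f_dbs: float, onset: float, total_time: float, amplitude: float) -> PulseTrain:
    """Conventional periodic DBS: events at onset + k/f_dbs below total_time."""
    if not f_dbs > 0:
        raise ValueError(f"f_dbs must be positive, got {f_dbs}")
    if not onset < total_time:
        raise ValueError("onset must precede total_time")
    period = 1.0 / f_dbs
    n = int(np.ceil((total_time - onset) / period))
    t = onset + period * np.arange(n + 1)
    return PulseTrain(t[t < total_time - 1e-12], amplitude, onset, total_time)


def _onset_burst(onset: float, total_time: float) -> np.ndarray:
    burst = onset + np.arange(BURST_PULSES) / BURST_HZ
    if burst[-1] >= total_time:
        raise ValueError(
            f"window [{onset}, {total_time}) too short for the "
            f"{BURST_PULSES}-pulse onset burst ({BURST_PULSES / BURST_HZ:.3f} s)"
        )
    return burst


def a_dbs(onset: float, total_time: float, amplitude: float) -> PulseTrain:
    """Onset burst (20 pulses at 130 Hz) then tonic 95 Hz pulsing.

    The first tonic event falls one tonic period (1/95 s) after the last
    burst pulse.
    """
    if not onset < total_time:
        raise ValueError("onset must precede total_time")
    burst = _onset_burst(onset, total_time)
    tonic_period = 1.0 / ADBS_TONIC_HZ
    start = burst[-1] + tonic_period
    n = max(0, int(np.ceil((total_time - start) / tonic_period)) + 1)
    tonic = start + tonic_period * np.arange(n)
    tonic = tonic[tonic < total_time - 1e-12]
    return PulseTrain(np.concatenate([burst, tonic]), amplitude, onset, total_time)


def b_dbs(
    onset: float,
    total_time: float,
    amplitude: float,
    pause_mode: str = "gap",
) -> PulseTrain:
    """Onset burst (20 pulses at 130 Hz) then repeating 4-pulse packs.

    pause_mode="gap" (default): 37 ms separates the last pulse of one
    pack (or of the onset burst) from the first pulse of the next pack,
    giving a pack period of 3/130 s + 37 ms ~ 60.1 ms (~16.6 packs/s).
    pause_mode="period": pack onsets repeat every 37 ms instead.
    Packs are truncated at total_time.
    """
    if not onset < total_time:
        raise ValueError("onset must precede total_time")
    if pause_mode not in ("gap", "period"):
        raise ValueError(f"unknown pause_mode {pause_mode!r}")
    burst = _onset_burst(onset, total_time)
    intra = 1.0 / BURST_HZ
    events = list(burst)
    if pause_mode == "gap":
        pack_start = events[-1] + BDBS_PAUSE_S
    else:
        pack_start = events[-1] + intra + BDBS_PAUSE_S
    while pack_start < total_time - 1e-12:
        for k in range(BDBS_PACK_PULSES):
            t = pack_start + k * intra
            if t >= total_time - 1e-12:
                break
            events.append(t)
        if pause_mode == "gap":
            pack_start = pack_start + (BDBS_PACK_PULSES - 1) * intra + BDBS_PAUSE_S
        else:
            pack_start = pack_start + BDBS_PAUSE_S
    return PulseTrain(np.asarray(events), amplitude, onset, total_time)


def scale_amplitude(train: PulseTrain, factor: float) -> PulseTrain:
    """Same event times, amplitude multiplied by ``factor`` (> 0)."""
    if not factor > 0:
        raise ValueError(f"factor must be positive, got {factor}")
    return replace(train, amplitude=train.amplitude * factor)


def select_targets(d_population_size: int, fraction: float, seed: int) -> np.ndarray:
    """Seeded random subset of layer-D indices receiving the stimulus.

    Size is the population size times ``fraction`` rounded to nearest;
    the default experiment uses fraction 0.5 (half the layer).
    """
    if d_population_size < 1:
        raise ValueError("population must contain at least one neuron")
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must lie in (0, 1], got {fraction}")
    k = int(round(fraction * d_population_size))
    if k < 1:
        raise ValueError("selection would be empty")
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(d_population_size, size=k, replace=False))


def inject(train: PulseTrain, dt: float) -> np.ndarray:
    """Discretize the train onto the simulation grid.

    ``dt`` is in ms; the returned waveform covers [0, total_time) at that
    step, with each Dirac event realized as a single sample of height
    amplitude/dt at the nearest grid point (unit time-integral scaling).
    """
    if not dt > 0:
        raise ValueError(f"dt must be positive, got {dt}")
    dt_s = dt / 1000.0
    n = int(round(train.total_time / dt_s))
    wave = np.zeros(n)
    if len(train) == 0 or train.amplitude == 0.0:
        return wave
    idx = np.rint(train.event_times / dt_s).astype(np.int64)
    if np.any(idx < 0) or np.any(idx >= n):
        raise ValueError("pulse events fall outside the simulation window")
    np.add.at(wave, idx, train.amplitude / dt)
    return wave


def event_steps(train: PulseTrain, dt: float) -> np.ndarray:
    """Grid indices of the pulse events at step ``dt`` ms (kernel helper)."""
    if not dt > 0:
        raise ValueError(f"dt must be positive, got {dt}")
    return np.rint(train.event_times / (dt / 1000.0)).astype(np.int64)
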