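"""Tsodyks–Markram short-term synaptic plasticity.

Between presynaptic spikes the three state variables relax exponentially:
u (utilized resource fraction) decays to 0 with tau_f, x (available
neurotransmitter fraction) recovers to 1 with tau_d, and the postsynaptic
current I decays to 0 with tau_s.  Each presynaptic spike applies, in
order,

    u+ = u- + U (1 - u-)
    dI = A u+ x-          (added to I)
    x+ = x- - u+ x-

so facilitation acts through u, depression through x, and the PSC jump
uses the *updated* u with the *pre-jump* x.  Under sustained
high-frequency drive a depressing synapse (large U, long tau_d) runs out
of resources and its per-spike PSC collapses — the synaptic-suppression
mechanism that makes high-frequency stimulation disconnect the
stimulated population from its targets.

``event_driven_psc_sequence`` evaluates the jump/decay map exactly at
spike times (closed-form exponentials between events) and serves as the
oracle against which the time-stepped integration is validated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SynapseParams",
    "SynapseState",
    "TM_CATEGORIES",
    "decay_step",
    "on_presynaptic_spike",
    "event_driven_psc_sequence",
    "periodic_steady_state",
]


@dataclass(frozen=True)
class SynapseParams:
    """U: utilization increment in [0,1]; tau_f/tau_d/tau_s: decay constants
    (ms) of u, x and I; A: absolute synaptic response (signed; negative for
    inhibitory channels)."""

    U: float
    tau_f: float
    tau_d: float
    tau_s: float
    A: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.U <= 1.0:
            raise ValueError(f"U must lie in [0, 1], got {self.U}")
        for name in ("tau_f", "tau_d", "tau_s"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")


@dataclass(frozen=True)
class SynapseState:
    u: float = 0.0
    x: float = 1.0
    I: float = 0.0


#: Canonical short-term plasticity classes (facilitating, depressing,
#: pseudo-linear).  tau_s defaults to a fast AMPA-like PSC decay; the
#: network config overrides A and tau_s per projection.
TM_CATEGORIES: dict[str, dict] = {
    "facilitating": dict(U=0.09, tau_f=670.0, tau_d=138.0, tau_s=3.0),
    "depressing": dict(U=0.50, tau_f=17.0, tau_d=671.0, tau_s=3.0),
    "pseudo_linear": dict(U=0.29, tau_f=326.0, tau_d=329.0, tau_s=3.0),
}


def decay_step(
    state: SynapseState, params: SynapseParams, dt: float, mode: str = "exact"
) -> SynapseState:
    """Advance the spike-free dynamics by ``dt`` ms.

    mode="exact" uses the closed-form exponentials of the linear ODEs;
    mode="euler" takes a single forward-Euler step (the scheme the
    network integrator mirrors).
    """
    if not dt > 0:
        raise ValueError(f"dt must be positive, got {dt}")
    if mode == "exact":
        eu = math.exp(-dt / params.tau_f)
        ex = math.exp(-dt / params.tau_d)
        es = math.exp(-dt / params.tau_s)
        return SynapseState(
            u=state.u * eu,
            x=1.0 - (1.0 - state.x) * ex,
            I=state.I * es,
        )
    if mode == "euler":
        return SynapseState(
            u=state.u + dt * (-state.u / params.tau_f),
            x=state.x + dt * ((1.0 - state.x) / params.tau_d),
            I=state.I + dt * (-state.I / params.tau_s),
        )
    raise ValueError(f"unknown mode {mode!r}; use 'exact' or 'euler'")


def on_presynaptic_spike(
    state: SynapseState, params: SynapseParams
) -> tuple[SynapseState, float]:
    """Apply the spike jumps; returns the new state and the PSC increment."""
    u_plus = state.u + params.U * (1.0 - state.u)
    dI = params.A * u_plus * state.x
    x_plus = state.x - u_plus * state.x
    return SynapseState(u=u_plus, x=x_plus, I=state.I + dI), dI


def event_driven_psc_sequence(
    params: SynapseParams,
    spike_times: "np.ndarray | list[float]",
    initial: SynapseState | None = None,
) -> np.ndarray:
    """Exact per-spike PSC increments for an arbitrary spike train (ms).

    Decays u and x analytically across each inter-spike interval and
    applies the jump rules at each spike; this is the closed-form
    solution of the jump/decay map and the reference the stepped
    simulation is checked against.
    """
    t = np.asarray(spike_times, dtype=float)
    if t.ndim != 1:
        raise ValueError("spike_times must be one-dimensional")
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise ValueError("spike_times must be strictly increasing")
    state = initial if initial is not None else SynapseState()
    u, x = state.u, state.x
    out = np.empty(t.size)
    prev = None
    for i, ti in enumerate(t):
        if prev is not None:
            dt = ti - prev
            u = u * math.exp(-dt / params.tau_f)
            x = 1.0 - (1.0 - x) * math.exp(-dt / params.tau_d)
        u = u + params.U * (1.0 - u)
        out[i] = params.A * u * x
        x = x - u * x
        prev = ti
    return out


def periodic_steady_state(params: SynapseParams, rate_hz: float) -> tuple[float, float, float]:
    """Fixed point (u*, x*, dI*) of the one-period return map under a
    periodic train at ``rate_hz``, evaluated just before each spike.

    Solves the affine pre-spike recursions
        u_pre' = (u_pre + U (1 - u_pre)) Ef
        x_pre' = 1 - (1 - x_pre (1 - u+)) Ed
    with Ef = exp(-T/tau_f), Ed = exp(-T/tau_d), T = 1000/rate_hz ms,
    and returns the steady per-spike PSC increment dI* = A u+* x_pre*.
    """
    if not rate_hz > 0:
        raise ValueError("rate must be positive")
    T = 1000.0 / rate_hz
    Ef = math.exp(-T / params.tau_f)
    Ed = math.exp(-T / params.tau_d)
    U = params.U
    # pre-spike u fixed point: u = (u + U(1-u)) Ef
    u_pre = U * Ef / (1.0 - (1.0 - U) * Ef)
    u_plus = u_pre + U * (1.0 - u_pre)
    # pre-spike x fixed point: x = 1 - (1 - x (1 - u+)) Ed
    x_pre = (1.0 - Ed) / (1.0 - (1.0 - u_plus) * Ed)
    return u_plus, x_pre, params.A * u_plus * x_pre
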