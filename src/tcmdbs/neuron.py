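"""Izhikevich single-neuron dynamics with a noisy spike-cutoff reset.

The membrane model is the two-variable quadratic integrate-and-reset system

    dv/dt = 0.04 v^2 + 5 v + 140 - u + I
    du/dt = a (b v - u)

with the reset rule: when v crosses ``v_peak`` plus a per-step Gaussian
threshold jitter, v is set to ``c`` and u is incremented by ``d``.  The four
parameters (a, b, c, d) select the firing phenotype (regular spiking,
fast spiking, thalamocortical relay, ...); the network uses heterogeneous
per-neuron draws around the canonical category values so that no two
neurons are identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "NeuronParams",
    "NeuronState",
    "CELL_CATEGORIES",
    "step_neuron",
    "make_heterogeneous_params",
]


@dataclass(frozen=True)
class NeuronParams:
    """Izhikevich parameters for one neuron.

    a : recovery rate (1/ms); b : recovery sensitivity (dimensionless);
    c : reset voltage (mV); d : recovery increment after a spike;
    v_peak : nominal spike cutoff (mV); I_bias : constant bias current.
    """

    a: float
    b: float
    c: float
    d: float
    v_peak: float = 30.0
    I_bias: float = 0.0

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError(f"a must be positive, got {self.a}")
        if not self.v_peak > self.c:
            raise ValueError(f"v_peak ({self.v_peak}) must exceed reset c ({self.c})")


@dataclass(frozen=True)
class NeuronState:
    """Membrane voltage v (mV) and recovery variable u."""

    v: float
    u: float


#: Canonical Izhikevich cell categories.  ``excitatory`` decides which
#: heterogeneity rule applies (see :func:`make_heterogeneous_params`).
CELL_CATEGORIES: dict[str, dict] = {
    "RS": dict(a=0.02, b=0.2, c=-65.0, d=8.0, excitatory=True),    # regular spiking
    "IB": dict(a=0.02, b=0.2, c=-55.0, d=4.0, excitatory=True),    # intrinsically bursting
    "FS": dict(a=0.10, b=0.2, c=-65.0, d=2.0, excitatory=False),   # fast spiking
    "LTS": dict(a=0.02, b=0.25, c=-65.0, d=2.0, excitatory=False),  # low-threshold spiking
    "TC": dict(a=0.02, b=0.25, c=-65.0, d=0.05, excitatory=True),  # thalamocortical relay
    "TRN": dict(a=0.02, b=0.25, c=-65.0, d=2.05, excitatory=False),  # reticular
}


def step_neuron(
    state: NeuronState,
    params: NeuronParams,
    total_input: float,
    dt: float,
    threshold_noise_draw: float = 0.0,
) -> tuple[NeuronState, bool]:
    """One forward-Euler step of the membrane equations plus the reset rule.

    ``total_input`` must already contain every current source (bias,
    synaptic, membrane noise, stimulation); the bias stored in ``params``
    is *not* added here, so callers keep full control of the drive.

    Returns the new state and a flag that is True iff the post-update
    voltage reached ``v_peak + threshold_noise_draw`` and was reset.
    """
    if not dt > 0:
        raise ValueError(f"dt must be positive, got {dt}")
    if not (math.isfinite(state.v) and math.isfinite(state.u) and math.isfinite(total_input)):
        raise ValueError(
            f"non-finite state or input: v={state.v}, u={state.u}, I={total_input}"
        )
    v, u = state.v, state.u
    v_new = v + dt * (0.04 * v * v + 5.0 * v + 140.0 - u + total_input)
    u_new = u + dt * params.a * (params.b * v - u)
    if v_new >= params.v_peak + threshold_noise_draw:
        return NeuronState(v=params.c, u=u_new + params.d), True
    return NeuronState(v=v_new, u=u_new), False


def resting_state(params: NeuronParams, total_input: float = 0.0) -> NeuronState:
    """Stable fixed point of the subthreshold dynamics, if it exists.

    Solves 0.04 v^2 + (5 - b) v + 140 + I = 0 (with u = b v on the
    u-nullcline) and returns the lower (stable) root.  Raises if the
    drive is above rheobase and no real fixed point exists.
    """
    b = params.b
    disc = (5.0 - b) ** 2 - 4.0 * 0.04 * (140.0 + total_input)
    if disc < 0:
        raise ValueError("input above rheobase: no subthreshold fixed point")
    v = (-(5.0 - b) - math.sqrt(disc)) / (2 * 0.04)
    return NeuronState(v=v, u=b * v)


def make_heterogeneous_params(
    category: str,
    n: int,
    seed: int,
    spread: float = 1.0,
    v_peak: float = 30.0,
    I_bias: float = 0.0,
) -> list[NeuronParams]:
    """Draw ``n`` non-identical parameter records for one cell category.

    The randomization follows the canonical Izhikevich network recipe:
    excitatory cells perturb the reset (c = c0 + 15 r^2 and
    d = d0 (1 - 0.75 r^2), interpolating toward bursting phenotypes),
    inhibitory cells perturb the recovery dynamics (a = a0 + 0.08 r,
    b = b0 - 0.05 r), with r uniform on [0, 1).  The d-perturbation is
    multiplicative so that it reproduces the classic regular-spiking
    range (8 - 6 r^2) while remaining positive for categories whose
    base d is small (bursting cortical and relay cells); an additive
    -6 r^2 would flip d negative there and abolish spike adaptation.
    ``spread`` scales r; spread = 0 returns the unmodified category
    parameters (useful for deterministic tests).
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    try:
        base = CELL_CATEGORIES[category]
    except KeyError:
        raise ValueError(
            f"unknown cell category {category!r}; known: {sorted(CELL_CATEGORIES)}"
        ) from None
    rng = np.random.default_rng(seed)
    r = spread * rng.random(n)
    out = []
    for ri in r:
        if base["excitatory"]:
            p = NeuronParams(
                a=base["a"], b=base["b"],
                c=base["c"] + 15.0 * ri * ri,
                d=base["d"] * (1.0 - 0.75 * ri * ri),
                v_peak=v_peak, I_bias=I_bias,
            )
        else:
            p = NeuronParams(
                a=base["a"] + 0.08 * ri,
                b=base["b"] - 0.05 * ri,
                c=base["c"], d=base["d"],
                v_peak=v_peak, I_bias=I_bias,
            )
        out.append(p)
    return out
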