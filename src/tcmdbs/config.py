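"""Default network description and YAML configuration I/O.

The exact coupling weights, transmission delays and per-projection
synapse parameters of the thalamocortical microcircuit are not fixed by
a single canonical source; the defaults below are a documented
reconstruction, chosen once so the unstimulated network reproduces the
Parkinsonian baseline the model is meant to exhibit — elevated
beta-band (13-30 Hz) LFP power carried by periodic population-wide
synchronized events, generated by the delayed cortico-thalamo-cortical
loop (D -> TCR -> D) under inhibitory control from TRN and CI.  Every
number here can be overridden from a YAML file.
"""

from __future__ import annotations

from dataclasses import asdict

import yaml

from .network import (
    NetworkConfig,
    NoiseConfig,
    PopulationSpec,
    Projection,
    SimulationConfig,
)

__all__ = [
    "default_network_config",
    "default_simulation_config",
    "load_config",
    "save_config",
]

#: Default stimulation amplitude (Dirac weight, model current units x ms).
#: The pulse amplitude that 1:1-entrains the directly stimulated D neurons
#: at 130 Hz is about twice this (see experiments.calibrate_amplitude); the
#: default operating point sits in the partial-entrainment regime, where
#: the identity of the pulsing pattern — not just its mean pulse rate —
#: shapes the network response.  Override via config or CLI.
DEFAULT_DBS_AMPLITUDE = 38.0


def default_populations() -> tuple:
    return (
        PopulationSpec("S", 100, {"RS": 0.5, "IB": 0.5}, excitatory=True, I_bias=2.5),
        PopulationSpec("M", 100, {"RS": 1.0}, excitatory=True, I_bias=2.5),
        PopulationSpec("D", 100, {"RS": 0.7, "IB": 0.3}, excitatory=True, I_bias=2.5),
        PopulationSpec("CI", 100, {"FS": 0.5, "LTS": 0.5}, excitatory=False, I_bias=2.5),
        PopulationSpec("TCR", 100, {"TC": 1.0}, excitatory=True, I_bias=0.0),
        PopulationSpec("TRN", 40, {"TRN": 1.0}, excitatory=False, I_bias=0.2),
    )


def default_projections() -> tuple:
    """Reconstructed coupling matrix (weight, delay, plasticity class).

    Excitatory pyramidal-to-pyramidal pathways are depressing — the
    substrate of the synaptic-suppression mechanism of high-frequency
    stimulation; excitatory drive onto interneurons is facilitating;
    inhibitory pathways are pseudo-linear with a slower PSC decay.
    Cortico-thalamic and thalamo-cortical delays are long (conduction
    through the internal capsule), which sets the beta-period loop time.
    """
    ct_delay = 13.0  # cortex <-> thalamus conduction + synaptic delay (ms)
    gaba = dict(plasticity="pseudo_linear", tau_s=11.0)
    return (
        # intracortical excitation (fast local delays)
        Projection("S", "S", 37.5, 1.0, "depressing"),
        Projection("S", "M", 75.0, 1.0, "depressing"),
        Projection("S", "D", 37.5, 1.0, "depressing"),
        Projection("M", "S", 37.5, 1.0, "depressing"),
        Projection("M", "M", 37.5, 1.0, "depressing"),
        Projection("M", "D", 75.0, 1.0, "depressing"),
        Projection("D", "S", 37.5, 1.0, "depressing"),
        Projection("D", "M", 37.5, 1.0, "depressing"),
        Projection("D", "D", 75.0, 1.0, "depressing"),
        # cortical inhibition
        Projection("S", "CI", 112.5, 1.0, "facilitating"),
        Projection("M", "CI", 112.5, 1.0, "facilitating"),
        Projection("D", "CI", 112.5, 1.0, "facilitating"),
        Projection("CI", "S", 225.0, 1.0, **gaba),
        Projection("CI", "M", 225.0, 1.0, **gaba),
        Projection("CI", "D", 225.0, 1.0, **gaba),
        Projection("CI", "CI", 37.5, 1.0, **gaba),
        # cortico-thalamo-cortical loop (beta-period delays)
        Projection("D", "TCR", 150.0, ct_delay, "depressing"),
        Projection("D", "TRN", 112.5, ct_delay, "facilitating"),
        Projection("TCR", "D", 225.0, ct_delay, "depressing"),
        Projection("TCR", "TRN", 112.5, 2.0, "facilitating"),
        Projection("TRN", "TCR", 450.0, 2.0, **gaba),
        Projection("TRN", "TRN", 37.5, 1.0, **gaba),
    )


def default_network_config(seed: int = 0) -> NetworkConfig:
    return NetworkConfig(
        populations=default_populations(),
        projections=default_projections(),
        noise=NoiseConfig(),
        seed=seed,
    )


def default_simulation_config(seed: int = 0, **overrides) -> SimulationConfig:
    return SimulationConfig(seed=seed, **overrides)


def save_config(config: NetworkConfig, path) -> None:
    """Serialize a network config to YAML."""
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)


def load_config(path) -> NetworkConfig:
    """Load a network config from YAML (as written by :func:`save_config`)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    try:
        pops = tuple(PopulationSpec(**p) for p in raw["populations"])
        projs = tuple(Projection(**p) for p in raw["projections"])
        noise = NoiseConfig(**raw.get("noise", {}))
        seed = int(raw.get("seed", 0))
    except (KeyError, TypeError, ValueError) as exc:
        raise ValueError(f"malformed network config {path}: {exc}") from exc
    return NetworkConfig(populations=pops, projections=projs, noise=noise, seed=seed)
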