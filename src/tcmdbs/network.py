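"""Thalamocortical microcircuit assembly and simulation.

The network contains six populations: three excitatory cortical layers
(S surface, M middle, D deep), a shared cortical interneuron pool (CI),
and the two thalamic populations (TCR relay, excitatory; TRN reticular,
inhibitory) — 540 neurons at the default sizes (100 each, TRN 40).
Neurons follow Izhikevich dynamics with heterogeneous parameters and
are coupled all-to-all (per-projection connection probability and
random weight dispersion) through Tsodyks–Markram synapses with
per-projection transmission delays.  Stimulation current is injected
into a seeded random half of the D layer.

Setting a population size to 0 deactivates that population and every
projection touching it.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from . import _kernel
from .neuron import CELL_CATEGORIES, make_heterogeneous_params
from .patterns import PulseTrain, event_steps, select_targets
from .synapse import TM_CATEGORIES, SynapseParams
from .synchrony import RasterMatrix

__all__ = [
    "PopulationSpec",
    "Projection",
    "NoiseConfig",
    "SimulationConfig",
    "NetworkConfig",
    "Network",
    "SimulationResult",
    "build_network",
    "simulate",
    "raster_to_matrix",
]

POPULATION_NAMES = ("S", "M", "D", "CI", "TCR", "TRN")


@dataclass(frozen=True)
class PopulationSpec:
    """One population: size, cell-category mix and bias current.

    ``categories`` maps Izhikevich category labels to mixing fractions
    (they must sum to 1); ``excitatory`` fixes the sign of the
    population's outgoing synapses.
    """

    name: str
    size: int
    categories: dict = field(default_factory=dict)
    excitatory: bool = True
    I_bias: float = 0.0
    param_spread: float = 1.0

    def __post_init__(self) -> None:
        if self.size < 0:
            raise ValueError("population size must be >= 0")
        if self.size > 0:
            if not self.categories:
                raise ValueError(f"population {self.name}: no cell categories")
            total = sum(self.categories.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"population {self.name}: category fractions sum to {total}"
                )
            for cat in self.categories:
                if cat not in CELL_CATEGORIES:
                    raise ValueError(f"unknown cell category {cat!r}")


@dataclass(frozen=True)
class Projection:
    """Directed population-to-population pathway.

    ``weight`` is the expected *total* synaptic weight converging on one
    postsynaptic neuron (individual connections are scaled by the
    expected in-degree); ``delay_ms`` is the summed synaptic + axonal
    transmission delay; ``plasticity`` names a TM category
    (facilitating / depressing / pseudo_linear) whose parameters can be
    overridden field-by-field via ``synapse_overrides``.
    """

    pre: str
    post: str
    weight: float
    delay_ms: float
    plasticity: str = "depressing"
    tau_s: float | None = None
    p_connect: float = 1.0
    weight_jitter: float = 0.4
    synapse_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError("projection weight is a magnitude; sign comes from the presynaptic population")
        if self.delay_ms < 0:
            raise ValueError("delay must be >= 0")
        if not 0.0 < self.p_connect <= 1.0:
            raise ValueError("p_connect must lie in (0, 1]")
        if self.plasticity not in TM_CATEGORIES:
            raise ValueError(f"unknown plasticity category {self.plasticity!r}")

    def synapse_params(self, sign: float) -> SynapseParams:
        base = dict(TM_CATEGORIES[self.plasticity])
        if self.tau_s is not None:
            base["tau_s"] = self.tau_s
        base.update(self.synapse_overrides)
        return SynapseParams(A=sign, **base)


@dataclass(frozen=True)
class NoiseConfig:
    """Membrane white noise xi (mV-scale sd, mean 0) and threshold jitter
    zeta (mV sd).  The Poissonian background input of the full model is
    represented by the flag only and is not simulated."""

    membrane_noise_sd: float = 0.5
    threshold_noise_sd: float = 0.1
    poisson_background: bool = False

    def __post_init__(self) -> None:
        if self.membrane_noise_sd < 0 or self.threshold_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.poisson_background:
            raise NotImplementedError(
                "Poissonian background noise is represented in the data model "
                "but intentionally not simulated"
            )


#: Reference step at which the configured membrane-noise sd applies
#: directly; other steps scale the per-step kick by sqrt(dt / dt_ref).
NOISE_DT_REF_MS = 0.1


@dataclass(frozen=True)
class SimulationConfig:
    dt_ms: float = 0.1
    duration_s: float = 12.0
    dbs_onset_s: float = 6.0
    seed: int = 0
    target_fraction: float = 0.5
    record_voltages: bool = False
    voltage_stride_ms: float = 1.0
    spike_capacity: int = 8_000_000

    def __post_init__(self) -> None:
        if not self.dt_ms > 0:
            raise ValueError("dt must be positive")
        if not self.dbs_onset_s < self.duration_s:
            raise ValueError("dbs_onset must precede the end of the simulation")


@dataclass(frozen=True)
class NetworkConfig:
    populations: tuple
    projections: tuple
    noise: NoiseConfig = NoiseConfig()
    seed: int = 0

    def __post_init__(self) -> None:
        names = [p.name for p in self.populations]
        if sorted(names) != sorted(set(names)):
            raise ValueError("duplicate population names")
        missing = set(POPULATION_NAMES) - set(names)
        if missing:
            raise ValueError(f"populations must cover {POPULATION_NAMES}; missing {sorted(missing)}")
        active = {p.name for p in self.populations if p.size > 0}
        for pr in self.projections:
            if pr.pre not in names or pr.post not in names:
                raise ValueError(f"projection {pr.pre}->{pr.post} references unknown population")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


class Network:
    """Flattened, simulation-ready realization of a NetworkConfig."""

    def __init__(self, config: NetworkConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        pops = list(config.populations)
        self.pop_names = [p.name for p in pops]
        self.population_index = {p.name: i for i, p in enumerate(pops)}
        sizes = np.array([p.size for p in pops], dtype=np.int64)
        self.pop_sizes = sizes
        self.pop_offsets = np.concatenate([[0], np.cumsum(sizes)])
        self.n_neurons = int(sizes.sum())
        self.pop_id = np.zeros(self.n_neurons, dtype=np.int32)
        for i in range(len(pops)):
            self.pop_id[self.pop_offsets[i]: self.pop_offsets[i + 1]] = i

        # heterogeneous neuron parameters, drawn per population / category
        N = self.n_neurons
        self.a = np.empty(N)
        self.b = np.empty(N)
        self.c = np.empty(N)
        self.d = np.empty(N)
        self.vpeak = np.full(N, 30.0)
        self.ibias = np.empty(N)
        for i, p in enumerate(pops):
            lo = self.pop_offsets[i]
            counts = _category_counts(p)
            pos = lo
            for cat, cnt in counts:
                params = make_heterogeneous_params(
                    cat, cnt, seed=int(rng.integers(2**31)),
                    spread=p.param_spread, I_bias=p.I_bias,
                )
                for q in params:
                    self.a[pos], self.b[pos], self.c[pos], self.d[pos] = q.a, q.b, q.c, q.d
                    self.ibias[pos] = q.I_bias
                    pos += 1

        # connections, grouped by presynaptic neuron (CSR)
        proj_params: list[SynapseParams] = []
        proj_delay: list[float] = []
        pre_list, post_list, w_list, proj_list = [], [], [], []
        exc = {p.name: p.excitatory for p in pops}
        for pr in config.projections:
            i_pre = self.population_index[pr.pre]
            i_post = self.population_index[pr.post]
            n_pre, n_post = sizes[i_pre], sizes[i_post]
            if n_pre == 0 or n_post == 0 or pr.weight == 0.0:
                continue
            sign = 1.0 if exc[pr.pre] else -1.0
            proj_idx = len(proj_params)
            proj_params.append(pr.synapse_params(sign))
            proj_delay.append(pr.delay_ms)
            mask = rng.random((n_pre, n_post)) < pr.p_connect
            if pr.pre == pr.post:
                np.fill_diagonal(mask, False)
            pre_i, post_i = np.nonzero(mask)
            k = pre_i.size
            if k == 0:
                continue
            scale = pr.weight / (pr.p_connect * n_pre)
            w = scale * (1.0 + pr.weight_jitter * (2.0 * rng.random(k) - 1.0))
            pre_list.append(self.pop_offsets[i_pre] + pre_i)
            post_list.append(self.pop_offsets[i_post] + post_i)
            w_list.append(w)
            proj_list.append(np.full(k, proj_idx, dtype=np.int32))

        if pre_list:
            pre = np.concatenate(pre_list)
            order = np.argsort(pre, kind="stable")
            self.conn_pre = pre[order]
            self.conn_post = np.concatenate(post_list)[order].astype(np.int32)
            self.conn_w = np.concatenate(w_list)[order]
            self.conn_proj = np.concatenate(proj_list)[order].astype(np.int32)
        else:
            self.conn_pre = np.empty(0, dtype=np.int64)
            self.conn_post = np.empty(0, dtype=np.int32)
            self.conn_w = np.empty(0)
            self.conn_proj = np.empty(0, dtype=np.int32)
        self.conn_off = np.searchsorted(self.conn_pre, np.arange(N + 1)).astype(np.int64)
        self.n_connections = int(self.conn_pre.size)

        self.proj_params = proj_params
        self.proj_delay_ms = np.asarray(proj_delay)
        self.p_U = np.array([q.U for q in proj_params])
        self.p_tauf = np.array([q.tau_f for q in proj_params])
        self.p_taud = np.array([q.tau_d for q in proj_params])
        self.p_A = np.array([q.A for q in proj_params])  # sign only; magnitude in weights
        # channels: one per distinct (tau_s, sign)
        keys = sorted({(q.tau_s, q.A > 0) for q in proj_params})
        self.chan_tau_s = np.array([k[0] for k in keys]) if keys else np.empty(0)
        self.chan_exc = np.array([k[1] for k in keys], dtype=np.bool_) if keys else np.empty(0, dtype=np.bool_)
        chan_of = {k: i for i, k in enumerate(keys)}
        self.p_chan = np.array(
            [chan_of[(q.tau_s, q.A > 0)] for q in proj_params], dtype=np.int32
        )


def _category_counts(p: PopulationSpec) -> list[tuple[str, int]]:
    """Integer split of the population across its categories (largest first
    remainder assignment so the counts sum exactly to the size)."""
    items = list(p.categories.items())
    raw = [p.size * frac for _, frac in items]
    counts = [int(np.floor(x)) for x in raw]
    rem = p.size - sum(counts)
    order = np.argsort([c - x for x, c in zip(raw, counts)])
    for j in range(rem):
        counts[order[j]] += 1
    return [(cat, cnt) for (cat, _), cnt in zip(items, counts) if cnt > 0]


@dataclass
class SimulationResult:
    """Spike raster, per-population PSC sums and run metadata."""

    dt_ms: float
    duration_s: float
    spike_times_ms: np.ndarray
    spike_neurons: np.ndarray
    pop_id: np.ndarray
    pop_names: list
    population_index: dict
    psc_exc: np.ndarray
    psc_inh: np.ndarray
    dbs_targets: np.ndarray
    seed: int
    config_hash: str
    voltages: np.ndarray | None = None
    voltage_stride_ms: float | None = None

    @property
    def n_steps(self) -> int:
        return self.psc_exc.shape[1]

    @property
    def time_ms(self) -> np.ndarray:
        return np.arange(self.n_steps) * self.dt_ms

    @property
    def sampling_rate_hz(self) -> float:
        return 1000.0 / self.dt_ms

    def spikes_of(self, population: str) -> tuple[np.ndarray, np.ndarray]:
        """(times_ms, neuron ids) restricted to one population."""
        i = self.population_index[population]
        m = self.pop_id[self.spike_neurons] == i
        return self.spike_times_ms[m], self.spike_neurons[m]

    def raster_to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "time_ms": self.spike_times_ms,
                "neuron_id": self.spike_neurons,
                "population": [self.pop_names[i] for i in self.pop_id[self.spike_neurons]],
            }
        ).to_csv(path, index=False)


def build_network(config: NetworkConfig) -> Network:
    """Realize the connectivity and heterogeneous parameters; deterministic
    under the config seed."""
    return Network(config)


def simulate(
    network: Network,
    pulse_train: PulseTrain | None = None,
    config: SimulationConfig | None = None,
) -> SimulationResult:
    """Co-integrate all neurons and synapses under the given stimulation.

    The pulse train (if any) is injected into a seeded random fraction
    (default half) of the D population; every other neuron sees it only
    through the synaptic pathways.  Bitwise reproducible for a fixed
    config, network and seed.
    """
    config = config or SimulationConfig()
    dt = config.dt_ms
    n_steps = int(round(config.duration_s * 1000.0 / dt))
    N = network.n_neurons

    if pulse_train is not None and len(pulse_train):
        if pulse_train.total_time > config.duration_s + 1e-9:
            raise ValueError("pulse train window exceeds the simulation window")
        dbs_steps = np.sort(event_steps(pulse_train, dt))
        if dbs_steps.size and (dbs_steps[0] < 0 or dbs_steps[-1] >= n_steps):
            raise ValueError("pulse events fall outside the simulation window")
        dbs_amp_step = pulse_train.amplitude / dt
    else:
        dbs_steps = np.empty(0, dtype=np.int64)
        dbs_amp_step = 0.0

    target_mask = np.zeros(N, dtype=np.bool_)
    i_d = network.population_index["D"]
    n_d = int(network.pop_sizes[i_d])
    if n_d > 0:
        local = select_targets(n_d, config.target_fraction, seed=config.seed)
        targets = network.pop_offsets[i_d] + local
        target_mask[targets] = True
    else:
        targets = np.empty(0, dtype=np.int64)

    delay_steps = np.maximum(
        1, np.rint(network.proj_delay_ms / dt).astype(np.int64)
    )
    conn_delay = (
        delay_steps[network.conn_proj].astype(np.int32)
        if network.n_connections
        else np.empty(0, dtype=np.int32)
    )
    L = int(conn_delay.max()) + 1 if conn_delay.size else 1
    n_ch = max(1, network.chan_tau_s.size)
    chan_decay = (
        np.exp(-dt / network.chan_tau_s) if network.chan_tau_s.size else np.ones(1)
    )
    chan_exc = network.chan_exc if network.chan_exc.size else np.ones(1, dtype=np.bool_)

    # fresh neuron state at the subthreshold resting point (where one
    # exists given the bias); overdriven neurons start from their reset
    disc = (5.0 - network.b) ** 2 - 0.16 * (140.0 + network.ibias)
    v_rest = np.where(
        disc >= 0,
        (-(5.0 - network.b) - np.sqrt(np.abs(disc))) / 0.08,
        network.c,
    )
    v = v_rest.copy()
    u = network.b * v
    syn_u = np.zeros(network.n_connections)
    syn_x = np.ones(network.n_connections)
    syn_tlast = np.full(network.n_connections, -(10**9), dtype=np.int64)

    noise = network.config.noise
    noise_kick = noise.membrane_noise_sd * np.sqrt(dt / NOISE_DT_REF_MS)

    buf = np.zeros((L, n_ch, N))
    n_pop = len(network.pop_names)
    psc_exc = np.zeros((n_pop, n_steps))
    psc_inh = np.zeros((n_pop, n_steps))
    spike_step = np.zeros(config.spike_capacity, dtype=np.int64)
    spike_id = np.zeros(config.spike_capacity, dtype=np.int32)

    record_v = config.record_voltages
    v_stride = max(1, int(round(config.voltage_stride_ms / dt)))
    n_rec = (n_steps + v_stride - 1) // v_stride if record_v else 1
    vtrace = np.zeros((N, n_rec), dtype=np.float32)

    ns = _kernel.run_kernel(
        n_steps, dt, int(config.seed) % (2**31),
        network.a, network.b, network.c, network.d, network.vpeak, network.ibias,
        v, u, network.pop_id, n_pop,
        network.conn_off, network.conn_post, network.conn_w, conn_delay, network.conn_proj,
        network.p_U, network.p_tauf, network.p_taud, network.p_A, network.p_chan,
        chan_decay, chan_exc,
        syn_u, syn_x, syn_tlast,
        dbs_steps, dbs_amp_step, target_mask,
        noise_kick, noise.threshold_noise_sd,
        buf, psc_exc, psc_inh, spike_step, spike_id,
        record_v, v_stride, vtrace,
    )
    if ns == -1:
        raise RuntimeError(
            f"spike capacity {config.spike_capacity} exceeded; raise spike_capacity"
        )
    if ns < -1:
        t_fail = (-ns - 2) * dt
        raise FloatingPointError(f"membrane state became non-finite at t = {t_fail:.1f} ms")

    return SimulationResult(
        dt_ms=dt,
        duration_s=config.duration_s,
        spike_times_ms=spike_step[:ns] * dt,
        spike_neurons=spike_id[:ns].copy(),
        pop_id=network.pop_id,
        pop_names=list(network.pop_names),
        population_index=dict(network.population_index),
        psc_exc=psc_exc,
        psc_inh=psc_inh,
        dbs_targets=np.asarray(targets, dtype=np.int64),
        seed=config.seed,
        config_hash=network.config.config_hash(),
        voltages=vtrace if record_v else None,
        voltage_stride_ms=v_stride * dt if record_v else None,
    )


def raster_to_matrix(
    result: SimulationResult,
    window: tuple,
    signal: str = "spikes",
    bin_ms: float = 1.0,
) -> RasterMatrix:
    """P x N activity matrix over a [start, end) window (seconds).

    signal="spikes": binary 0/1 per (bin, neuron); signal="voltages":
    recorded membrane voltages resampled at the bin width (requires
    ``record_voltages`` and a compatible stride).  Columns are ordered by
    population then neuron index.
    """
    start_s, end_s = window
    if not 0.0 <= start_s < end_s <= result.duration_s + 1e-9:
        raise ValueError(f"empty or out-of-range window {window}")
    N = result.pop_id.size
    if signal == "spikes":
        P = int(round((end_s - start_s) * 1000.0 / bin_ms))
        if P < 1:
            raise ValueError("window shorter than one bin")
        m = (result.spike_times_ms >= start_s * 1000.0) & (
            result.spike_times_ms < start_s * 1000.0 + P * bin_ms
        )
        rows = ((result.spike_times_ms[m] - start_s * 1000.0) / bin_ms).astype(np.int64)
        rows = np.minimum(rows, P - 1)
        values = np.zeros((P, N))
        values[rows, result.spike_neurons[m]] = 1.0
    elif signal == "voltages":
        if result.voltages is None:
            raise ValueError("voltages were not recorded; set record_voltages")
        stride = result.voltage_stride_ms
        step = bin_ms / stride
        if abs(step - round(step)) > 1e-9 or round(step) < 1:
            raise ValueError(
                f"bin ({bin_ms} ms) must be a multiple of the voltage stride ({stride} ms)"
            )
        i0 = int(round(start_s * 1000.0 / stride))
        i1 = int(round(end_s * 1000.0 / stride))
        values = result.voltages[:, i0:i1:int(round(step))].T.astype(float)
        P = values.shape[0]
    else:
        raise ValueError(f"unknown signal choice {signal!r}")
    if P < 10 * N:
        warnings.warn(
            f"only {P} samples for {N} neurons; the synchrony metric "
            "prefers samples >> neurons",
            stacklevel=2,
        )
    labels = [result.pop_names[i] for i in result.pop_id]
    return RasterMatrix(values, bin_ms, labels)
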