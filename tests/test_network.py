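"""Network assembly, simulation determinism, raster extraction, numerical
robustness and the Parkinsonian baseline."""

from dataclasses import replace

import numpy as np
import pytest

from tcmdbs import (
    NetworkConfig,
    NoiseConfig,
    PopulationSpec,
    SimulationConfig,
    band_power,
    build_network,
    cdbs,
    compute_psd,
    default_network_config,
    estimate_lfp,
    simulate,
)
from tcmdbs.network import raster_to_matrix
from tcmdbs.neuron import resting_state, NeuronParams


def quiet_config(seed=0):
    """All populations at rest: no noise, no bias, default wiring."""
    cfg = default_network_config(seed=seed)
    pops = tuple(replace(p, I_bias=0.0) for p in cfg.populations)
    return NetworkConfig(
        populations=pops,
        projections=cfg.projections,
        noise=NoiseConfig(membrane_noise_sd=0.0, threshold_noise_sd=0.0),
        seed=seed,
    )


class TestBuild:
    def test_default_network_counts(self):
        net = build_network(default_network_config())
        assert net.n_neurons == 540
        assert net.pop_sizes[net.population_index["TRN"]] == 40

    def test_deactivating_m_removes_population_and_projections(self):
        cfg = default_network_config()
        pops = tuple(
            replace(p, size=0, categories={}) if p.name == "M" else p
            for p in cfg.populations
        )
        net = build_network(NetworkConfig(pops, cfg.projections, cfg.noise, cfg.seed))
        assert net.n_neurons == 440
        i_m = net.population_index["M"]
        assert not np.any(net.pop_id == i_m)
        # no M-originating connections survive
        assert all(
            net.conn_pre[net.conn_off[n]: net.conn_off[n + 1]].size == 0
            for n in range(net.n_neurons)
            if net.pop_id[n] == i_m
        )

    def test_build_deterministic_under_seed(self):
        a = build_network(default_network_config(seed=5))
        b = build_network(default_network_config(seed=5))
        assert np.array_equal(a.conn_w, b.conn_w)
        assert np.array_equal(a.c, b.c)


class TestSimulate:
    def test_identical_seeds_identical_rasters(self):
        net = build_network(default_network_config(seed=2))
        sim = SimulationConfig(duration_s=2.0, dbs_onset_s=1.0, seed=2)
        r1 = simulate(net, None, sim)
        r2 = simulate(net, None, sim)
        assert np.array_equal(r1.spike_times_ms, r2.spike_times_ms)
        assert np.array_equal(r1.spike_neurons, r2.spike_neurons)
        assert np.array_equal(r1.psc_exc, r2.psc_exc)

    def test_quiet_network_stays_silent(self):
        net = build_network(quiet_config())
        res = simulate(net, None, SimulationConfig(duration_s=1.0, dbs_onset_s=0.5, seed=0))
        assert res.spike_times_ms.size == 0
        assert np.all(res.psc_exc == 0.0) and np.all(res.psc_inh == 0.0)

    def test_dbs_targets_are_half_of_layer_d(self):
        net = build_network(default_network_config(seed=1))
        train = cdbs(130.0, 0.5, 1.0, amplitude=38.0)
        res = simulate(net, train, SimulationConfig(duration_s=1.0, dbs_onset_s=0.5, seed=1))
        i_d = net.population_index["D"]
        lo, hi = net.pop_offsets[i_d], net.pop_offsets[i_d + 1]
        assert res.dbs_targets.size == 50
        assert np.all((res.dbs_targets >= lo) & (res.dbs_targets < hi))

    def test_entraining_amplitude_drives_targets_at_pulse_rate(self):
        # at roughly the 1:1-calibrated amplitude the directly stimulated
        # D neurons follow the 130 Hz train
        net = build_network(default_network_config(seed=1))
        train = cdbs(130.0, 0.25, 1.25, amplitude=80.0)
        res = simulate(net, train, SimulationConfig(duration_s=1.25, dbs_onset_s=0.25, seed=1))
        t = res.spike_times_ms
        on = (t >= 250.0) & (t < 1250.0)
        counts = np.bincount(res.spike_neurons[on], minlength=net.n_neurons)
        rate = counts[res.dbs_targets].mean()
        assert 120.0 <= rate <= 140.0

    def test_spike_capacity_overflow_reported(self):
        net = build_network(default_network_config(seed=0))
        sim = SimulationConfig(duration_s=1.0, dbs_onset_s=0.5, seed=0, spike_capacity=10)
        with pytest.raises(RuntimeError, match="capacity"):
            simulate(net, None, sim)

    def test_pulse_train_outside_window_rejected(self):
        net = build_network(default_network_config(seed=0))
        train = cdbs(130.0, 0.5, 2.0, amplitude=10.0)
        with pytest.raises(ValueError, match="window"):
            simulate(net, train, SimulationConfig(duration_s=1.0, dbs_onset_s=0.5, seed=0))


class TestRasterMatrix:
    def test_binary_spike_matrix_shape_and_values(self):
        net = build_network(default_network_config(seed=3))
        res = simulate(net, None, SimulationConfig(duration_s=2.0, dbs_onset_s=1.0, seed=3))
        gamma = raster_to_matrix(res, (0.0, 2.0), bin_ms=1.0)
        assert gamma.values.shape == (2000, 540)
        assert set(np.unique(gamma.values)) <= {0.0, 1.0}

    def test_voltage_columns_settle_at_fixed_points_when_quiet(self):
        net = build_network(quiet_config())
        res = simulate(
            net, None,
            SimulationConfig(duration_s=2.0, dbs_onset_s=1.0, seed=0,
                             record_voltages=True),
        )
        gamma = raster_to_matrix(res, (1.5, 2.0), signal="voltages", bin_ms=1.0)
        # every column is flat and equals the analytic resting voltage
        assert np.max(gamma.values.std(axis=0)) < 0.05
        for n in range(0, net.n_neurons, 97):
            p = NeuronParams(a=net.a[n], b=net.b[n], c=net.c[n], d=net.d[n])
            v_star = resting_state(p).v
            assert gamma.values[-1, n] == pytest.approx(v_star, abs=0.5)

    def test_empty_window_rejected(self):
        net = build_network(default_network_config(seed=0))
        res = simulate(net, None, SimulationConfig(duration_s=1.0, dbs_onset_s=0.5, seed=0))
        with pytest.raises(ValueError, match="window"):
            raster_to_matrix(res, (0.8, 0.8))


class TestBaselineDynamics:
    def test_beta_power_stable_under_dt_halving(self):
        def beta(dt, seed):
            net = build_network(default_network_config(seed=seed))
            res = simulate(net, None, SimulationConfig(dt_ms=dt, duration_s=6.0,
                                                       dbs_onset_s=3.0, seed=seed))
            lfp = estimate_lfp(res)
            return band_power(compute_psd(lfp, res.sampling_rate_hz))

        seeds = range(1, 6)
        coarse = np.median([beta(0.1, s) for s in seeds])
        fine = np.median([beta(0.05, s) for s in seeds])
        assert abs(fine - coarse) / coarse < 0.15

    def test_beta_fraction_exceeds_weight_shuffled_control(self):
        # the Parkinsonian baseline rests on the structured coupling:
        # permuting which pathway carries which weight degrades the
        # beta-band share of the LFP spectrum
        def beta_fraction(cfg, seed):
            net = build_network(cfg)
            res = simulate(net, None, SimulationConfig(duration_s=6.0,
                                                       dbs_onset_s=3.0, seed=seed))
            psd = compute_psd(estimate_lfp(res), res.sampling_rate_hz)
            return band_power(psd) / band_power(psd, 1.0, 100.0)

        structured, shuffled = [], []
        for seed in range(1, 6):
            cfg = default_network_config(seed=seed)
            rng = np.random.default_rng(100 + seed)
            weights = [p.weight for p in cfg.projections]
            perm = rng.permutation(len(weights))
            projs = tuple(
                replace(p, weight=weights[j]) for p, j in zip(cfg.projections, perm)
            )
            structured.append(beta_fraction(cfg, seed))
            shuffled.append(
                beta_fraction(NetworkConfig(cfg.populations, projs, cfg.noise, seed), seed)
            )
        assert np.median(structured) > np.median(shuffled)
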