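"""Numba time-stepping kernel for the thalamocortical network.

Membrane dynamics are integrated by forward Euler; synapses are handled
event-wise with exact inter-spike exponentials (the same closed form as
the event-driven oracle in :mod:`tcmdbs.synapse`), so per-connection
state is only touched when its presynaptic neuron fires.  Postsynaptic
currents are aggregated per neuron into a small number of decay
channels (one per distinct PSC time constant and sign), and delayed
delivery goes through a circular (delay-slot, channel, neuron) buffer.

Single-threaded by design: the spike loop mutates shared buffers, and
run-to-run determinism under a fixed seed is part of the contract.
"""

import numpy as np
from numba import njit

__all__ = ["run_kernel"]


@njit(cache=True)
def run_kernel(
    n_steps,
    dt,
    seed,
    # neurons
    a, b, c, d, vpeak, ibias, v, u, pop_id, n_pop,
    # connectivity (CSR by presynaptic neuron)
    conn_off, conn_post, conn_w, conn_delay, conn_proj,
    # projection TM parameters
    p_U, p_tauf, p_taud, p_A, p_chan,
    # channels
    chan_decay, chan_exc,
    # TM state per connection
    syn_u, syn_x, syn_tlast,
    # stimulation
    dbs_steps, dbs_amp_step, target_mask,
    # noise
    noise_kick, thr_sd,
    # delayed-delivery buffer and outputs
    buf, psc_exc, psc_inh, spike_step, spike_id,
    record_v, v_stride, vtrace,
):
    np.random.seed(seed)
    N = v.shape[0]
    n_ch = chan_decay.shape[0]
    L = buf.shape[0]
    cap = spike_step.shape[0]
    I_ch = np.zeros((n_ch, N))
    dbs_ptr = 0
    n_dbs = dbs_steps.shape[0]
    ns = 0
    for k in range(n_steps):
        slot = k % L
        # decay channel currents and pick up arrivals scheduled for this step
        for ch in range(n_ch):
            dec = chan_decay[ch]
            for n in range(N):
                I_ch[ch, n] = I_ch[ch, n] * dec + buf[slot, ch, n]
                buf[slot, ch, n] = 0.0
        # per-population PSC sums (signed; exc channels positive)
        for p in range(n_pop):
            psc_exc[p, k] = 0.0
            psc_inh[p, k] = 0.0
        for ch in range(n_ch):
            if chan_exc[ch]:
                for n in range(N):
                    psc_exc[pop_id[n], k] += I_ch[ch, n]
            else:
                for n in range(N):
                    psc_inh[pop_id[n], k] += I_ch[ch, n]
        # stimulation current for this step (Dirac weight A over one step)
        dbs_now = 0.0
        while dbs_ptr < n_dbs and dbs_steps[dbs_ptr] == k:
            dbs_now += dbs_amp_step
            dbs_ptr += 1
        rec = record_v and (k % v_stride == 0)
        col = k // v_stride
        for n in range(N):
            I_syn = 0.0
            for ch in range(n_ch):
                I_syn += I_ch[ch, n]
            I_tot = ibias[n] + I_syn
            if dbs_now != 0.0 and target_mask[n]:
                I_tot += dbs_now
            vv = v[n]
            uu = u[n]
            v_new = (
                vv + dt * (0.04 * vv * vv + 5.0 * vv + 140.0 - uu + I_tot)
                + noise_kick * np.random.normal(0.0, 1.0)
            )
            u_new = uu + dt * a[n] * (b[n] * vv - uu)
            zeta = thr_sd * np.random.normal(0.0, 1.0)
            cutoff = vpeak[n] + zeta
            if v_new >= cutoff:
                if ns >= cap:
                    return -1
                spike_step[ns] = k
                spike_id[ns] = n
                ns += 1
                v[n] = c[n]
                u[n] = u_new + d[n]
                if rec:
                    vtrace[n, col] = cutoff  # clamp: record the cut spike apex
                # deliver to all outgoing connections (event-driven TM update)
                for ci in range(conn_off[n], conn_off[n + 1]):
                    pr = conn_proj[ci]
                    el = (k - syn_tlast[ci]) * dt
                    us = syn_u[ci] * np.exp(-el / p_tauf[pr])
                    xs = 1.0 - (1.0 - syn_x[ci]) * np.exp(-el / p_taud[pr])
                    us = us + p_U[pr] * (1.0 - us)
                    dI = p_A[pr] * conn_w[ci] * us * xs
                    syn_x[ci] = xs - us * xs
                    syn_u[ci] = us
                    syn_tlast[ci] = k
                    buf[(k + conn_delay[ci]) % L, p_chan[pr], conn_post[ci]] += dI
            else:
                if not np.isfinite(v_new):
                    return -2 - k  # encode failure time
                v[n] = v_new
                u[n] = u_new
                if rec:
                    vtrace[n, col] = v_new
    return ns
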