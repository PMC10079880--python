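"""Numba-compiled integration loop for the pulse-coupled network.

The two pools are concatenated into one state vector (pool 1 first, excitatory
neurons first within each pool).  Recurrent and cross-pool couplings live in a
single CSC matrix over the combined index space, so spike delivery is a scan
over the presynaptic neuron's column.  Spikes fired during a step are
delivered to postsynaptic voltages at the start of the next step, making the
within-step update order irrelevant.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def run_network(
    n_steps,
    dt,
    g_L,
    V_Re,
    V_floor,
    lam,
    phi,
    v,
    th,
    th0,
    adapt,
    Iff,
    indptr,
    indices,
    data,
    bin_steps,
    counts,
    vsum,
    thsum,
    resetsum,
    clampsum,
    nsamp,
    sample_every,
    gid,
    gcount,
    th_trace,
    record_full_th,
    th_full,
    record_spikes,
    spike_t,
    spike_i,
):
    T = v.shape[0]
    n_bins = counts.shape[1]
    pend = np.zeros(T)
    n_rec = 0
    n_total = 0
    cap = spike_t.shape[0]

    # sample the initial state (sample index 0, stats bin 0)
    for g in range(4):
        th_trace[0, g] = 0.0
    for i in range(T):
        vsum[i, 0] += v[i]
        thsum[i, 0] += th[i]
        th_trace[0, gid[i]] += th[i]
        if record_full_th:
            th_full[0, i] = th[i]
    nsamp[0] += 1
    for g in range(4):
        th_trace[0, g] /= gcount[g]

    for step in range(n_steps):
        b = step // bin_steps
        if b >= n_bins:
            b = n_bins - 1
        t_spike = (step + 1) * dt
        for i in range(T):
            # deliver impulses from the previous step, then integrate
            vi = v[i] + pend[i]
            pend[i] = 0.0
            vi += dt * (Iff[i] - g_L * (vi - V_Re))
            if adapt[i]:
                th[i] += dt * lam * (th0[i] - th[i])
            if vi < V_floor:
                clampsum[i, b] += V_floor - vi
                vi = V_floor  # hyperpolarization bounded at reversal
            if vi >= th[i]:
                # spike: reset, jump threshold, queue deliveries
                resetsum[i, b] += vi - V_Re
                vi = V_Re
                if adapt[i]:
                    th[i] += phi
                counts[i, b] += 1
                n_total += 1
                if record_spikes and n_rec < cap:
                    spike_t[n_rec] = t_spike
                    spike_i[n_rec] = i
                    n_rec += 1
                for p in range(indptr[i], indptr[i + 1]):
                    pend[indices[p]] += data[p]
            v[i] = vi
        if (step + 1) % sample_every == 0:
            s = (step + 1) // sample_every
            nsamp[b] += 1
            g0 = 0.0
            g1 = 0.0
            g2 = 0.0
            g3 = 0.0
            for i in range(T):
                vsum[i, b] += v[i]
                thsum[i, b] += th[i]
                g = gid[i]
                if g == 0:
                    g0 += th[i]
                elif g == 1:
                    g1 += th[i]
                elif g == 2:
                    g2 += th[i]
                else:
                    g3 += th[i]
                if record_full_th:
                    th_full[s, i] = th[i]
            th_trace[s, 0] = g0 / gcount[0]
            th_trace[s, 1] = g1 / gcount[1]
            th_trace[s, 2] = g2 / gcount[2]
            th_trace[s, 3] = g3 / gcount[3]
    return n_rec, n_total


@njit(cache=True)
def accumulate_ei(indptr, indices, data, counts_total, acc_exc, acc_inh):
    """Cumulative excitatory/inhibitory synaptic input per postsynaptic neuron.

    Exact bookkeeping from total spike counts per presynaptic neuron: every
    spike of neuron j delivers column j once.
    """
    T = counts_total.shape[0]
    for j in range(T):
        cj = counts_total[j]
        if cj == 0:
            continue
        for p in range(indptr[j], indptr[j + 1]):
            w = data[p] * cj
            if w > 0:
                acc_exc[indices[p]] += w
            else:
                acc_inh[indices[p]] += w
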