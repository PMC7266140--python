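"""Compiled inner loops of the time-stepped simulator.

One global step loop advances every neuron of the flattened network.  Spikes
are delivered as delta voltage jumps through a circular (delay-slot, neuron)
buffer; pair-based STDP is applied event-wise using exponential traces per
plastic connection group:

* at each presynaptic spike, edges of groups with ``alpha != 0`` are updated
  from the postsynaptic trace (post-before-pre pairings, excluding spikes of
  the current step),
* at each postsynaptic spike, incoming plastic edges are updated from the
  presynaptic trace (pre-before-post pairings, including same-step pairs,
  which count as ``dt = 0``).

Pairings are evaluated at spike *emission* times; the constant ``-A_minus``
offset applies once per triggering spike.  Traces decay by a precomputed
per-step factor, so the incremental bookkeeping reproduces the brute-force
sum over spike pairs to floating-point accuracy.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["seed_rng", "run_steps"]


@njit(cache=True)
def seed_rng(seed):  # pragma: no cover - trivial
    np.random.seed(seed)


@njit(cache=True)
def run_steps(
    t0, t1, dt_s, psp_scale,
    # neuron state (length n_real)
    V, b_sfa, refr_remaining,
    # neuron constants
    vm_dec, bias_term, lock_flag, c1, c2, c3,
    sfa_dec, q_sfa, b_cap, refr_steps,
    # delivery ring (L, n_real)
    ring,
    # edges (flat, CSR by presynaptic id over n_real + n_x sources)
    csr_indptr, e_pre, e_post, e_dstep, e_grp, e_w,
    # plastic edges CSC by postsynaptic id (n_real + 1)
    pl_indptr, pl_eids,
    # per-group plasticity parameters
    g_eta, g_alpha, g_Aminus, g_wmin, g_wmax, g_gate,
    g_pre_off, g_pre_base, g_pre_size,
    g_post_off, g_post_base, g_post_size,
    # traces
    trace_val, trace_dec,
    # input population
    p_x,
    # output buffers
    out_ids, out_steps, n_out0,
    # scratch (n_real + n_x)
    spk_buf,
):
    n_real = V.shape[0]
    n_x = p_x.shape[0]
    L = ring.shape[0]
    n_groups = g_eta.shape[0]
    m_tr = trace_val.shape[0]
    n_out = n_out0
    cap = out_ids.shape[0]

    for t in range(t0, t1):
        if n_out + n_real + n_x > cap:
            return t, n_out

        slot = t % L

        # trace decay
        for k in range(m_tr):
            trace_val[k] *= trace_dec[k]

        # membrane update, hazard, spike sampling; locked neurons behave
        # like refractory ones (no integration, no spikes, inputs discarded)
        n_spk = 0
        for i in range(n_real):
            b_sfa[i] *= sfa_dec[i]
            if refr_remaining[i] > 0:
                refr_remaining[i] -= 1
                V[i] = 0.0
                continue
            if lock_flag[i] == 1:
                V[i] = 0.0
                continue
            v = vm_dec[i] * V[i] + bias_term[i] + ring[slot, i]
            V[i] = v
            veff = v + b_sfa[i]
            rho = c1[i] * veff
            if c2[i] != 0.0:
                rho += c2[i] * (np.exp(c3[i] * veff) - 1.0)
            if rho > 0.0:
                p = -np.expm1(-rho * dt_s)
                if np.random.random() < p:
                    spk_buf[n_spk] = i
                    n_spk += 1
                    V[i] = 0.0
                    refr_remaining[i] = refr_steps[i]
                    b = b_sfa[i] + q_sfa[i]
                    if b > b_cap[i]:
                        b = b_cap[i]
                    b_sfa[i] = b

        # clear used delivery slot
        for i in range(n_real):
            ring[slot, i] = 0.0

        # input population spikes
        for k in range(n_x):
            if p_x[k] > 0.0 and np.random.random() < p_x[k]:
                spk_buf[n_spk] = n_real + k
                n_spk += 1

        # record
        for s in range(n_spk):
            out_ids[n_out] = spk_buf[s]
            out_steps[n_out] = t
            n_out += 1

        # pass A: delivery + post-before-pre updates (uses post traces
        # without the current step's postsynaptic spikes)
        for s in range(n_spk):
            j = spk_buf[s]
            for e in range(csr_indptr[j], csr_indptr[j + 1]):
                tgt = e_post[e]
                ring[(t + e_dstep[e]) % L, tgt] += psp_scale * e_w[e]
                g = e_grp[e]
                if g_alpha[g] != 0.0 and g_gate[g] == 1:
                    xpost = trace_val[g_post_off[g] + tgt - g_post_base[g]]
                    w = e_w[e] + g_eta[g] * g_alpha[g] * (xpost - g_Aminus[g])
                    if w < g_wmin[g]:
                        w = g_wmin[g]
                    elif w > g_wmax[g]:
                        w = g_wmax[g]
                    e_w[e] = w

        # presynaptic trace increments (before pass B so that same-step
        # pre/post pairs enter the dt >= 0 branch with exp(0) = 1)
        for s in range(n_spk):
            j = spk_buf[s]
            for g in range(n_groups):
                d = j - g_pre_base[g]
                if 0 <= d < g_pre_size[g]:
                    trace_val[g_pre_off[g] + d] += 1.0

        # pass B: pre-before-post updates at postsynaptic spikes
        for s in range(n_spk):
            j = spk_buf[s]
            if j >= n_real:
                continue
            for k in range(pl_indptr[j], pl_indptr[j + 1]):
                e = pl_eids[k]
                g = e_grp[e]
                if g_gate[g] == 1:
                    xpre = trace_val[g_pre_off[g] + e_pre[e] - g_pre_base[g]]
                    w = e_w[e] + g_eta[g] * (xpre - g_Aminus[g])
                    if w < g_wmin[g]:
                        w = g_wmin[g]
                    elif w > g_wmax[g]:
                        w = g_wmax[g]
                    e_w[e] = w

        # postsynaptic trace increments
        for s in range(n_spk):
            j = spk_buf[s]
            for g in range(n_groups):
                if g_post_off[g] < 0:
                    continue
                d = j - g_post_base[g]
                if 0 <= d < g_post_size[g]:
                    trace_val[g_post_off[g] + d] += 1.0

    return t1, n_out


@njit(cache=True)
def lif_readout(spike_steps, spike_syn, syn_w_eff, n_steps, dt,
                tau_m, v_rest, v_thresh, refr_steps, n_neurons, syn_post):
    """Leaky integrate-and-fire readout population driven by delta synapses.

    ``spike_steps``/``spike_syn`` list presynaptic events per incoming
    synapse (sorted by step); ``syn_w_eff`` carries the per-event efficacy-
    scaled voltage jump.  After a spike the membrane is clamped at rest for
    the refractory period.  Returns (neuron_ids, step_indices) of readout
    spikes.  Deterministic (threshold units).
    """
    v = np.full(n_neurons, v_rest)
    refr = np.zeros(n_neurons, dtype=np.int64)
    dec = np.exp(-dt / tau_m)
    out_n = []
    out_t = []
    ev = 0
    n_ev = spike_steps.shape[0]
    for t in range(n_steps):
        for i in range(n_neurons):
            if refr[i] > 0:
                refr[i] -= 1
                v[i] = v_rest
            else:
                v[i] = v_rest + dec * (v[i] - v_rest)
        while ev < n_ev and spike_steps[ev] == t:
            s = spike_syn[ev]
            i = syn_post[s]
            if refr[i] == 0:
                v[i] += syn_w_eff[ev]
            ev += 1
        for i in range(n_neurons):
            if refr[i] == 0 and v[i] >= v_thresh:
                out_n.append(i)
                out_t.append(t)
                v[i] = v_rest
                refr[i] = refr_steps
    ids = np.empty(len(out_n), dtype=np.int32)
    steps = np.empty(len(out_n), dtype=np.int64)
    for k in range(len(out_n)):
        ids[k] = out_n[k]
        steps[k] = out_t[k]
    return ids, steps
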