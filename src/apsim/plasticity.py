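"""Pair-based STDP with offset, gating logic, and short-term depression.

The pairing rule: a presynaptic spike at ``t_pre`` and a postsynaptic spike
at ``t_post`` with ``dt = t_post - t_pre`` contribute

* ``eta * (exp(-dt/tau_plus) - A_minus)``            for ``dt >= 0``,
* ``eta * |alpha| * (exp(-|dt|/tau_minus) - A_minus)`` for ``dt < 0``
  (zero for connection types without an anti-causal branch, ``alpha = 0``).

Both branches share the coincidence-minus-offset shape: near-coincident
firing potentiates, while every triggering spike also pays the constant
``-A_minus`` offset against the full exponential trace of its partner
train.  The net drift is therefore positive exactly when the partner's
rate exceeds ``A_minus / tau`` -- high-rate co-activation potentiates and
saturates at the bound, background-rate pairing slowly depresses to zero.
``alpha``'s tabulated sign encodes the branch orientation used during
parameter fitting; the engine normalizes it so that the anti-causal window
is coincidence-potentiating (see docs/methods.md for why the literal sign
cannot form assemblies).

Updates are applied at each triggering spike (all-to-all in the exponential
term, one offset per spike) at spike emission times, and the weight is
clipped to ``[w_min, w_max]`` after every update.  Plasticity of any group
touching a neural space is gated by that space's disinhibition; groups
frozen by protocol never update.
"""

from __future__ import annotations

import numpy as np

from .params import STDPParams, TMParams


def stdp_delta(dt_pair: float, params: STDPParams) -> float:
    """Weight change for a single pairing with ``dt = t_post - t_pre``.

    ``dt = 0`` counts as a causal pairing.
    """
    if not np.isfinite(dt_pair):
        raise ValueError("pairing interval must be finite")
    if dt_pair >= 0:
        return params.eta * (np.exp(-dt_pair / params.tau_plus) - params.A_minus)
    if params.alpha == 0.0 or params.tau_minus is None:
        return 0.0
    return (params.eta * abs(params.alpha)
            * (np.exp(dt_pair / params.tau_minus) - params.A_minus))


def pairing_updates_bruteforce(pre_times, post_times,
                               params: STDPParams) -> float:
    """Total (unclipped) weight change by the quadratic all-pairs sum.

    Independent oracle for the trace-based bookkeeping: each postsynaptic
    spike sums ``exp(-dt/tau_plus)`` over every earlier (or simultaneous)
    presynaptic spike explicitly and pays the offset once; with an
    anti-causal branch each presynaptic spike does the symmetric sum over
    strictly earlier postsynaptic spikes.
    """
    total = 0.0
    for tp in np.asarray(post_times, float):
        s = sum(np.exp(-(tp - tq) / params.tau_plus)
                for tq in np.asarray(pre_times, float) if tq <= tp)
        total += params.eta * (s - params.A_minus)
    if params.alpha != 0.0:
        for tq in np.asarray(pre_times, float):
            s = sum(np.exp(-(tq - tp) / params.tau_minus)
                    for tp in np.asarray(post_times, float) if tp < tq)
            total += (params.eta * abs(params.alpha) * (s - params.A_minus))
    return total


def apply_pairings(pre_spikes, post_spikes, edges, weights,
                   params: STDPParams, *, gate_open: bool = True,
                   t_window=None):
    """Offline application of the pairing rule to a sparse edge group.

    Parameters
    ----------
    pre_spikes, post_spikes
        ``(neuron_index, time_ms)`` tuples of arrays for the pre- and
        postsynaptic populations.
    edges
        ``(pre_index, post_index)`` arrays defining the group.
    weights
        Per-edge weights, updated in place (clipped to the group bounds
        after each triggering spike).
    t_window
        Optional ``(t0, t1)``; spikes outside raise ``ValueError``.

    Uses incremental exponential traces, equivalent to the brute-force
    all-pairs computation to floating-point accuracy.  Returns ``weights``.
    """
    pre_i, pre_t = (np.asarray(a) for a in pre_spikes)
    post_i, post_t = (np.asarray(a) for a in post_spikes)
    if t_window is not None:
        t0, t1 = t_window
        for t in (pre_t, post_t):
            if len(t) and (t.min() < t0 or t.max() > t1):
                raise ValueError("spike outside the simulated window")
    if not gate_open or (len(pre_t) == 0 and len(post_t) == 0):
        return weights
    e_pre, e_post = (np.asarray(a) for a in edges)
    n_pre = int(max(pre_i.max(initial=-1), e_pre.max(initial=-1))) + 1
    n_post = int(max(post_i.max(initial=-1), e_post.max(initial=-1))) + 1

    in_edges = [[] for _ in range(n_post)]   # post -> edge ids
    out_edges = [[] for _ in range(n_pre)]
    for k in range(len(e_pre)):
        in_edges[e_post[k]].append(k)
        out_edges[e_pre[k]].append(k)

    # merge the two spike streams in time; pre spikes of equal time first so
    # that dt = 0 pairings land in the causal branch
    events = [(t, 0, i) for i, t in zip(pre_i, pre_t)]
    events += [(t, 1, i) for i, t in zip(post_i, post_t)]
    events.sort(key=lambda e: (e[0], e[1]))

    x_pre = np.zeros(n_pre)
    t_pre = np.zeros(n_pre)
    x_post = np.zeros(n_post)
    t_post = np.zeros(n_post)
    use_anti = params.alpha != 0.0 and params.tau_minus is not None

    for t, kind, i in events:
        if kind == 0:
            if use_anti:
                for k in out_edges[i]:
                    j = e_post[k]
                    xp = x_post[j] * np.exp(-(t - t_post[j]) / params.tau_minus)
                    w = weights[k] + (params.eta * abs(params.alpha)
                                      * (xp - params.A_minus))
                    weights[k] = min(max(w, params.w_min), params.w_max)
            x_pre[i] = x_pre[i] * np.exp(-(t - t_pre[i]) / params.tau_plus) + 1.0
            t_pre[i] = t
        else:
            for k in in_edges[i]:
                q = e_pre[k]
                xq = x_pre[q] * np.exp(-(t - t_pre[q]) / params.tau_plus)
                w = weights[k] + params.eta * (xq - params.A_minus)
                weights[k] = min(max(w, params.w_min), params.w_max)
            if use_anti:
                x_post[i] = (x_post[i]
                             * np.exp(-(t - t_post[i]) / params.tau_minus) + 1.0)
                t_post[i] = t
    return weights


def set_gates(engine, *, induction_frozen: bool = True) -> None:
    """Synchronize plasticity gates with the current inhibition state.

    Every plastic group with an endpoint in a neural space S is open
    exactly when S is disinhibited; the input and recurrent connections of
    the content space are permanently frozen once induction is over.
    """
    if induction_frozen:
        for grp in engine.net.groups:
            if grp.plastic and not grp.touched_neural_spaces:
                engine.frozen.add(grp.name)
    engine._sync_locks_gates()


def tm_efficacy(spike_times, params: TMParams) -> np.ndarray:
    """Per-spike release efficacy of a dynamic (depressing) synapse.

    Standard two-variable release/recovery recursion: utilization ``u``
    facilitates with ``tau_fac`` and resources ``x`` recover with
    ``tau_rec``.  The first spike of a long-rested synapse releases
    ``U * 1``; rapid stimulation depresses towards the closed-form steady
    state of the recursion.
    """
    t = np.asarray(spike_times, float)
    if len(t) > 1 and np.any(np.diff(t) <= 0):
        raise ValueError("spike times must be strictly increasing")
    u, x = params.U, 1.0
    eff = np.empty(len(t))
    for k in range(len(t)):
        if k > 0:
            dt = t[k] - t[k - 1]
            x = 1.0 - (1.0 - x) * np.exp(-dt / params.tau_rec)
            u = params.U + (u - params.U) * np.exp(-dt / params.tau_fac)
        eff[k] = u * x
        x -= u * x
        u = u + params.U * (1.0 - u)
    return eff


def tm_steady_state(rate_hz: float, params: TMParams) -> float:
    """Closed-form steady-state efficacy under periodic stimulation."""
    dt = 1000.0 / rate_hz
    eu = np.exp(-dt / params.tau_fac)
    u_ss = params.U / (1 - (1 - params.U) * eu)
    er = np.exp(-dt / params.tau_rec)
    x_ss = (1 - er) / (1 - (1 - u_ss) * er)
    return u_ss * x_ss
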