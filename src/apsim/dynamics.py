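"""Stochastic point-neuron dynamics: reference operations and the engine.

The neuron model is a discrete-time stochastic unit: the membrane potential
relaxes exponentially (time constant ``tau_m``) towards ``R_m * I`` and each
delivered spike adds an instantaneous voltage jump.  A neuron spikes in a
step of length ``dt`` with probability ``1 - exp(-rho * dt)`` where the
hazard ``rho = c1*V' + c2*(exp(c3*V') - 1)`` (clipped at zero) depends on
the effective potential ``V' = V + b_sfa``.  After a spike the membrane is
reset to zero and the neuron is refractory for a per-neuron fixed duration;
the excitability bias ``b_sfa`` increments by ``q_sfa`` (clipped at
``b_sfa_max``) and decays with ``tau_sfa``.

:class:`Engine` runs the compiled whole-network loop (see
:mod:`apsim._kernels`); the module-level functions are the single-step
reference implementations used for unit-level validation.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .params import DT_MS, NeuronParams, PSP_SCALE, V_LOCK_CLAMP


# --------------------------------------------------------------------------
# Reference single-population operations
# --------------------------------------------------------------------------

def instantaneous_rate(V_eff, params: NeuronParams):
    """Hazard (Hz) at effective membrane potential ``V_eff`` (mV).

    Negative values of the rate expression are clipped to zero: the
    expression defines a hazard, not a signed quantity.
    """
    V_eff = np.asarray(V_eff, dtype=float)
    if not np.all(np.isfinite(V_eff)):
        raise FloatingPointError("non-finite membrane potential")
    rho = params.c1 * V_eff + params.c2 * np.expm1(params.c3 * V_eff)
    return np.maximum(rho, 0.0)


@dataclass
class PopulationState:
    """Per-neuron dynamic state of one population."""

    V: np.ndarray               # mV
    b_sfa: np.ndarray           # mV
    refr_remaining: np.ndarray  # ms
    refr_duration: np.ndarray   # ms, fixed per neuron

    @classmethod
    def zeros(cls, n: int, refr_duration) -> "PopulationState":
        refr = np.broadcast_to(np.asarray(refr_duration, float), (n,)).copy()
        if np.any(refr <= 0):
            raise ValueError("refractory durations must be positive")
        return cls(V=np.zeros(n), b_sfa=np.zeros(n),
                   refr_remaining=np.zeros(n), refr_duration=refr)


def membrane_step(state: PopulationState, I_syn, I_inh,
                  params: NeuronParams, dt: float = DT_MS) -> PopulationState:
    """Advance membrane potentials one step under constant currents (nA).

    Refractory neurons stay clamped at the post-spike reset value (0 mV)
    until their remaining refractory time expires.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    dec = np.exp(-dt / params.tau_m)
    drive = (1.0 - dec) * params.R_m * (np.asarray(I_syn, float)
                                        + np.asarray(I_inh, float) + params.I_e)
    V = dec * state.V + drive
    refr = state.refr_remaining > 0
    V[refr] = 0.0
    state.V = V
    state.refr_remaining = np.maximum(state.refr_remaining - dt, 0.0)
    state.b_sfa = state.b_sfa * np.exp(-dt / params.tau_sfa)
    return state


def sample_spikes(state: PopulationState, params: NeuronParams,
                  dt: float, rng: np.random.Generator) -> np.ndarray:
    """Draw spikes for one step; apply reset/refractoriness/excitability.

    Each non-refractory neuron spikes with probability ``1 - exp(-rho*dt)``
    (exact for a hazard constant within the step, never exceeding 1).
    """
    rho = instantaneous_rate(state.V + state.b_sfa, params)
    p = -np.expm1(-rho * dt * 1e-3)
    p[state.refr_remaining > 0] = 0.0
    spiked = rng.random(len(p)) < p
    state.V[spiked] = 0.0
    state.refr_remaining[spiked] = state.refr_duration[spiked]
    state.b_sfa[spiked] = np.minimum(state.b_sfa[spiked] + params.q_sfa,
                                     params.b_sfa_max)
    return spiked


# --------------------------------------------------------------------------
# Spike records
# --------------------------------------------------------------------------

@dataclass
class SpikeRecord:
    """Timestamped spike events over named populations.

    ``ids`` are global neuron indices; ``populations`` maps a population
    name to its ``(offset, size)`` slice of the global index range.
    """

    ids: np.ndarray    # int32 global neuron ids
    times: np.ndarray  # ms
    populations: dict[str, tuple[int, int]]

    def __len__(self) -> int:
        return len(self.ids)

    def window(self, t0: float, t1: float) -> "SpikeRecord":
        m = (self.times >= t0) & (self.times < t1)
        return SpikeRecord(self.ids[m], self.times[m], self.populations)

    def for_population(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        """(local neuron indices, spike times) of one population."""
        off, size = self.populations[name]
        m = (self.ids >= off) & (self.ids < off + size)
        return (self.ids[m] - off).astype(np.int64), self.times[m]

    def counts(self, name: str, t0: float | None = None,
               t1: float | None = None) -> np.ndarray:
        """Per-neuron spike counts of a population inside [t0, t1)."""
        off, size = self.populations[name]
        idx, times = self.for_population(name)
        if t0 is not None or t1 is not None:
            lo = -np.inf if t0 is None else t0
            hi = np.inf if t1 is None else t1
            m = (times >= lo) & (times < hi)
            idx = idx[m]
        return np.bincount(idx, minlength=size)

    def mean_rate(self, name: str, t0: float, t1: float) -> float:
        """Population-mean firing rate (Hz) inside [t0, t1)."""
        c = self.counts(name, t0, t1)
        return float(c.sum() / len(c) / ((t1 - t0) * 1e-3))

    def to_text(self, fh) -> None:
        """gdf-like columnar text: population, local index, time (ms)."""
        close = False
        if isinstance(fh, str):
            fh, close = open(fh, "w"), True
        try:
            for name, (off, size) in sorted(self.populations.items()):
                fh.write(f"# {name}\t{off}\t{size}\n")
            order = np.argsort(self.times, kind="stable")
            names = sorted(self.populations.items(), key=lambda kv: kv[1][0])
            offs = np.array([off for _, (off, _) in names])
            for k in order:
                gid, t = int(self.ids[k]), self.times[k]
                pi = int(np.searchsorted(offs, gid, side="right") - 1)
                name, (off, _) = names[pi]
                fh.write(f"{name}\t{gid - off}\t{t:.1f}\n")
        finally:
            if close:
                fh.close()

    def to_npz(self, path) -> None:
        """Structured-binary container for large runs."""
        names = sorted(self.populations)
        np.savez_compressed(
            path, ids=self.ids, times=self.times,
            pop_names=np.array(names),
            pop_offsets=np.array([self.populations[n][0] for n in names]),
            pop_sizes=np.array([self.populations[n][1] for n in names]))

    @classmethod
    def from_npz(cls, path) -> "SpikeRecord":
        d = np.load(path, allow_pickle=False)
        pops = {str(n): (int(o), int(s)) for n, o, s in
                zip(d["pop_names"], d["pop_offsets"], d["pop_sizes"])}
        return cls(d["ids"], d["times"], pops)

    @classmethod
    def from_text(cls, fh) -> "SpikeRecord":
        close = False
        if isinstance(fh, str):
            fh, close = open(fh), True
        try:
            pops, ids, times = {}, [], []
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    name, off, size = line[1:].split()
                    pops[name] = (int(off), int(size))
                    continue
                name, idx, t = line.split("\t")
                ids.append(pops[name][0] + int(idx))
                times.append(float(t))
            return cls(np.array(ids, dtype=np.int32), np.array(times),
                       pops)
        finally:
            if close:
                fh.close()


# --------------------------------------------------------------------------
# Engine
# --------------------------------------------------------------------------

class Engine:
    """Event-accurate whole-network simulation loop.

    Wraps the compiled step kernel around a :class:`~apsim.network.CompiledNetwork`.
    Lock state (the per-space inhibitory lock current) and plasticity gates
    are piecewise constant between calls to :meth:`advance`; protocols
    compose runs from such segments.  Identical seed and call sequence give
    bit-identical spike records.
    """

    def __init__(self, net, seed: int, dt: float = DT_MS,
                 psp_scale: float = PSP_SCALE):
        self.net = net
        self.dt = dt
        self.psp_scale = psp_scale
        self.t_step = 0
        self._chunks: list[tuple[np.ndarray, np.ndarray]] = []
        n = net.n_real
        self.V = np.zeros(n)
        self.b_sfa = np.zeros(n)
        self.refr_remaining = np.zeros(n, dtype=np.int32)
        self.ring = np.zeros((net.ring_len, n))
        self.trace_val = np.zeros_like(net.trace_dec)
        self._lock_flag = np.zeros(n, dtype=np.uint8)
        self._spk_buf = np.zeros(n + net.n_x, dtype=np.int64)
        self.locked: dict[str, bool] = {s.name: (s.kind == "neural")
                                        for s in net.spaces}
        self.frozen: set[str] = set()
        self.gates = np.zeros(net.n_groups, dtype=np.uint8)
        self._sync_locks_gates()
        _kernels.seed_rng(int(seed) & 0x7FFFFFFF)

    # -- control ------------------------------------------------------------

    @property
    def t_ms(self) -> float:
        return self.t_step * self.dt

    def set_lock(self, space: str, locked: bool) -> None:
        """Engage or lift the inhibitory lock of a space.

        Unlocking releases the space's membranes from the lock-clamp
        potential; their dynamics resume from there.
        """
        if space not in self.locked:
            raise KeyError(f"unknown space {space!r}")
        was = self.locked[space]
        self.locked[space] = bool(locked)
        if was != locked:
            for s in self.net.spaces:
                if s.name == space:
                    sl = slice(s.offset, s.offset + s.n_total)
                    # Input in flight towards a locking space is discarded
                    # (as during refractoriness).  A neural space also
                    # discards in-flight input when released: its retrieval
                    # cue is the excitability trace, and stale deliveries
                    # from the closing content space would otherwise
                    # detonate arbitrary neurons at the release instant.
                    # The content space keeps in-flight input at release --
                    # its release is the read-out moment whose purpose is
                    # to receive the feedback already en route.
                    if locked or s.kind == "neural":
                        self.ring[:, sl] = 0.0
                    if was:
                        self.V[sl] = V_LOCK_CLAMP
        self._sync_locks_gates()

    def freeze_group(self, name: str) -> None:
        """Permanently disable plasticity of a connection group."""
        if name not in self.net.group_index:
            raise KeyError(f"unknown group {name!r}")
        self.frozen.add(name)
        self._sync_locks_gates()

    def _sync_locks_gates(self) -> None:
        net = self.net
        self._lock_flag[:] = 0
        for s in net.spaces:
            if self.locked[s.name]:
                sl = slice(s.offset, s.offset + s.n_total)
                self._lock_flag[sl] = 1
        # Gating: a plastic group is open iff it is not frozen and every
        # neural space it touches is disinhibited.  The content-space lock
        # does not gate plasticity.
        for g, grp in enumerate(net.groups):
            if not grp.plastic:
                continue
            open_ = grp.name not in self.frozen
            for sp in grp.touched_neural_spaces:
                if self.locked[sp]:
                    open_ = False
            self.gates[g] = 1 if open_ else 0

    # -- simulation ---------------------------------------------------------

    def advance(self, duration_ms: float, x_rates=None) -> None:
        """Simulate for ``duration_ms`` with constant input rates (Hz)."""
        net = self.net
        n_steps = int(round(duration_ms / self.dt))
        if n_steps == 0:
            return
        if x_rates is None:
            x_rates = np.zeros(net.n_x)
        x_rates = np.asarray(x_rates, dtype=float)
        if x_rates.shape != (net.n_x,):
            raise ValueError("x_rates must match the input population size")
        p_x = -np.expm1(-x_rates * self.dt * 1e-3)

        t0, t1 = self.t_step, self.t_step + n_steps
        # conservative capacity: 250 Hz average over the chunk, grown on demand
        cap = max(10_000, int((net.n_real + net.n_x) * n_steps * self.dt
                              * 1e-3 * 250))
        while t0 < t1:
            out_ids = np.empty(cap, dtype=np.int32)
            out_steps = np.empty(cap, dtype=np.int64)
            t_reached, n_out = _kernels.run_steps(
                t0, t1, self.dt * 1e-3, self.psp_scale,
                self.V, self.b_sfa, self.refr_remaining,
                net.vm_dec, net.bias_term, self._lock_flag,
                net.c1, net.c2, net.c3,
                net.sfa_dec, net.q_sfa, net.b_cap, net.refr_steps,
                self.ring,
                net.csr_indptr, net.e_pre, net.e_post, net.e_dstep,
                net.e_grp, net.e_w,
                net.pl_indptr, net.pl_eids,
                net.g_eta, net.g_alpha, net.g_Aminus, net.g_wmin,
                net.g_wmax, self.gates,
                net.g_pre_off, net.g_pre_base, net.g_pre_size,
                net.g_post_off, net.g_post_base, net.g_post_size,
                self.trace_val, net.trace_dec,
                p_x, out_ids, out_steps, 0, self._spk_buf)
            if n_out:
                self._chunks.append((out_ids[:n_out].copy(),
                                     out_steps[:n_out].copy()))
            if t_reached < t1:
                cap *= 2
            t0 = t_reached
        self.t_step = t1

    def record(self, t0: float | None = None,
               t1: float | None = None) -> SpikeRecord:
        """Spike record of the whole run (or of the window [t0, t1))."""
        if self._chunks:
            ids = np.concatenate([c[0] for c in self._chunks])
            steps = np.concatenate([c[1] for c in self._chunks])
        else:
            ids = np.empty(0, dtype=np.int32)
            steps = np.empty(0, dtype=np.int64)
        rec = SpikeRecord(ids, (steps + 1) * self.dt, self.net.populations)
        if t0 is not None or t1 is not None:
            rec = rec.window(-np.inf if t0 is None else t0,
                             np.inf if t1 is None else t1)
        return rec

    def drop_record(self) -> None:
        """Discard accumulated spikes (state and weights are kept)."""
        self._chunks.clear()

    # -- weights ------------------------------------------------------------

    def weights(self, group: str):
        """(pre, post, w) triplets of one connection group (views)."""
        g = self.net.group_index[group]
        eids = self.net.group_eids[g]
        return (self.net.e_pre[eids], self.net.e_post[eids],
                self.net.e_w[eids])

    def save_weights(self, group: str, fh) -> None:
        """Sparse-triplet text snapshot of one group's weights."""
        close = False
        if isinstance(fh, str):
            fh, close = open(fh, "w"), True
        try:
            fh.write(f"# group={group} t_ms={self.t_ms:.1f}\n")
            pre, post, w = self.weights(group)
            for a, b, v in zip(pre, post, w):
                fh.write(f"{a}\t{b}\t{v:.9g}\n")
        finally:
            if close:
                fh.close()
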