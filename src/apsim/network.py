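"""Construction of content/neural spaces and all wiring.

A *space* is a pair of excitatory (E) and inhibitory (I) pools at a 4:1
size ratio with static E-I wiring and plastic recurrent E-E connections.
The content space C additionally receives all-to-all plastic input from the
external population X; every neural space S is bidirectionally and sparsely
(p = 0.1) connected with C through plastic synapses.  The inhibitory lock of
a space is realized as a strong negative current (-4 nA) applied to all of
its neurons when the space is inhibited.

Wiring randomness is drawn from per-component streams derived from the
master seed, so adding a neural space never perturbs the realization of the
content space.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .params import (DT_MS, EXC_PARAMS, INH_PARAMS,
                     NEURAL_EXC_PARAMS, STATIC_SCALE_CONTENT,
                     STATIC_SCALE_NEURAL, ConnectionTables, DEFAULT_TABLES,
                     STDPParams, StaticParams, gamma_refractory_durations)


def component_rng(master_seed: int, tag: str) -> np.random.Generator:
    """Independent, reproducible stream for one named network component."""
    return np.random.default_rng([int(master_seed), zlib.crc32(tag.encode())])


@dataclass
class Space:
    """Excitatory/inhibitory pool pair with an inhibitory lock."""

    name: str
    kind: str          # "content" | "neural"
    n_exc: int
    offset: int = 0    # global id of first excitatory neuron
    refr_exc: np.ndarray | None = None
    refr_inh: np.ndarray | None = None

    def __post_init__(self):
        if self.n_exc % 4:
            raise ValueError("n_exc must be divisible by 4 (E:I ratio 4:1)")

    @property
    def n_inh(self) -> int:
        return self.n_exc // 4

    @property
    def n_total(self) -> int:
        return self.n_exc + self.n_inh

    @property
    def exc_slice(self) -> slice:
        return slice(self.offset, self.offset + self.n_exc)

    @property
    def inh_slice(self) -> slice:
        return slice(self.offset + self.n_exc, self.offset + self.n_total)


@dataclass
class EdgeGroup:
    """One directed connection type as sparse (pre, post, weight) triplets."""

    name: str
    plastic: bool
    params: STDPParams | StaticParams
    pre: np.ndarray       # global ids
    post: np.ndarray
    delay_ms: np.ndarray
    w: np.ndarray
    pre_range: tuple[int, int]   # (base, size) of the presynaptic pool
    post_range: tuple[int, int]
    touched_neural_spaces: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.pre)


def bernoulli_pairs(n_pre: int, n_post: int, p: float,
                    rng: np.random.Generator,
                    exclude_self: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Independent Bernoulli(p) ordered pairs, optionally without i==i."""
    if p >= 1.0:
        pre, post = np.meshgrid(np.arange(n_pre), np.arange(n_post),
                                indexing="ij")
        pre, post = pre.ravel(), post.ravel()
        if exclude_self:
            keep = pre != post
            pre, post = pre[keep], post[keep]
        return pre.astype(np.int64), post.astype(np.int64)
    mask = rng.random((n_pre, n_post)) < p
    if exclude_self:
        np.fill_diagonal(mask, False)
    pre, post = np.nonzero(mask)
    return pre, post


class NetworkModel:
    """Incrementally assembled network; :meth:`compile` flattens it.

    The model can be extended (e.g. a neural space added after content-space
    training) and recompiled; trained weights live in the group arrays and
    survive recompilation.
    """

    def __init__(self, master_seed: int, tables: ConnectionTables = DEFAULT_TABLES,
                 n_in: int = 200, dt: float = DT_MS,
                 static_scale: dict[str, float] | None = None):
        self.master_seed = int(master_seed)
        self.tables = tables
        self.n_in = n_in
        self.dt = dt
        self.static_scale = dict(static_scale) if static_scale else {
            "content": STATIC_SCALE_CONTENT, "neural": STATIC_SCALE_NEURAL}
        self.spaces: list[Space] = []
        self.groups: list[EdgeGroup] = []
        self._n_real = 0

    # -- construction -------------------------------------------------------

    def space(self, name: str) -> Space:
        for s in self.spaces:
            if s.name == name:
                return s
        raise KeyError(f"unknown space {name!r}")

    @property
    def content(self) -> Space:
        return next(s for s in self.spaces if s.kind == "content")

    @property
    def neural_spaces(self) -> list[Space]:
        return [s for s in self.spaces if s.kind == "neural"]

    def add_content_space(self, name: str = "C", n_exc: int = 1000) -> Space:
        if any(s.kind == "content" for s in self.spaces):
            raise ValueError("network already has a content space")
        sp = self._add_space(name, "content", n_exc)
        self._wire_input(sp)
        return sp

    def add_neural_space(self, name: str, n_exc: int = 2000) -> Space:
        c = self.content  # requires a content space first
        sp = self._add_space(name, "neural", n_exc)
        self._wire_inter(c, sp)
        return sp

    def _add_space(self, name: str, kind: str, n_exc: int) -> Space:
        if any(s.name == name for s in self.spaces):
            raise ValueError(f"duplicate space name {name!r}")
        sp = Space(name=name, kind=kind, n_exc=n_exc, offset=self._n_real)
        rng = component_rng(self.master_seed, f"space:{name}")
        exc_p = NEURAL_EXC_PARAMS if kind == "neural" else EXC_PARAMS
        sp.refr_exc = gamma_refractory_durations(sp.n_exc, exc_p, rng)
        sp.refr_inh = gamma_refractory_durations(sp.n_inh, INH_PARAMS, rng)
        self._n_real += sp.n_total
        self.spaces.append(sp)
        self._wire_internal(sp, rng)
        return sp

    def _edge_group(self, name, params, pre_base, n_pre, post_base, n_post,
                    rng, *, plastic, exclude_self=False, touched=(),
                    space_kind=None):
        pre, post = bernoulli_pairs(n_pre, n_post, params.p, rng,
                                    exclude_self=exclude_self)
        n = len(pre)
        if plastic:
            lo, hi = params.clipped_init_bounds()
            w = rng.uniform(lo, hi, size=n) if hi > lo else np.full(n, lo)
            d = (rng.uniform(params.delay_lo, params.delay_hi, size=n)
                 if params.delay_hi > params.delay_lo
                 else np.full(n, params.delay_lo))
        else:
            w = np.full(n, params.w * self.static_scale[space_kind])
            d = np.full(n, params.delay)
        grp = EdgeGroup(
            name=name, plastic=plastic, params=params,
            pre=pre + pre_base, post=post + post_base,
            delay_ms=d, w=w,
            pre_range=(pre_base, n_pre), post_range=(post_base, n_post),
            touched_neural_spaces=tuple(touched))
        self.groups.append(grp)
        return grp

    def _wire_internal(self, sp: Space, rng: np.random.Generator) -> None:
        t = self.tables
        kind_key = "C" if sp.kind == "content" else "S"
        touched = (sp.name,) if sp.kind == "neural" else ()
        e0, i0 = sp.offset, sp.offset + sp.n_exc
        self._edge_group(f"{sp.name}.E->E", t.plastic_row(kind_key, "E->E"),
                         e0, sp.n_exc, e0, sp.n_exc, rng,
                         plastic=True, exclude_self=True, touched=touched)
        self._edge_group(f"{sp.name}.E->I", t.static["E->I"],
                         e0, sp.n_exc, i0, sp.n_inh, rng, plastic=False,
                         space_kind=sp.kind)
        self._edge_group(f"{sp.name}.I->E", t.static["I->E"],
                         i0, sp.n_inh, e0, sp.n_exc, rng, plastic=False,
                         space_kind=sp.kind)
        self._edge_group(f"{sp.name}.I->I", t.static["I->I"],
                         i0, sp.n_inh, i0, sp.n_inh, rng,
                         plastic=False, exclude_self=True,
                         space_kind=sp.kind)

    def _wire_input(self, c: Space) -> None:
        rng = component_rng(self.master_seed, "conn:X->C")
        # X occupies ids [n_real_at_compile, +n_in); use a placeholder base
        # resolved at compile time (stored as negative ids offset by -1).
        self._edge_group("X->C", self.tables.plastic_row("C", "X->E"),
                         -self.n_in - 1, self.n_in, c.offset, c.n_exc, rng,
                         plastic=True)

    def _wire_inter(self, c: Space, s: Space) -> None:
        rng_ff = component_rng(self.master_seed, f"conn:C->{s.name}")
        rng_fb = component_rng(self.master_seed, f"conn:{s.name}->C")
        self._edge_group(f"C->{s.name}", self.tables.plastic_row("S", "C->E"),
                         c.offset, c.n_exc, s.offset, s.n_exc, rng_ff,
                         plastic=True, touched=(s.name,))
        self._edge_group(f"{s.name}->C", self.tables.plastic_row("C", "S->E"),
                         s.offset, s.n_exc, c.offset, c.n_exc, rng_fb,
                         plastic=True, touched=(s.name,))

    # -- compilation --------------------------------------------------------

    def compile(self) -> "CompiledNetwork":
        return CompiledNetwork(self)


class CompiledNetwork:
    """Flat-array view of a :class:`NetworkModel` for the step kernel."""

    def __init__(self, model: NetworkModel):
        self.model = model
        self.spaces = model.spaces
        self.n_real = model._n_real
        self.n_x = model.n_in
        dt = model.dt

        self.populations: dict[str, tuple[int, int]] = {}
        for s in self.spaces:
            self.populations[f"{s.name}.E"] = (s.offset, s.n_exc)
            self.populations[f"{s.name}.I"] = (s.offset + s.n_exc, s.n_inh)
        self.populations["X"] = (self.n_real, self.n_x)

        # neuron constants
        n = self.n_real
        self.vm_dec = np.zeros(n)
        self.bias_term = np.zeros(n)
        self.c1 = np.zeros(n)
        self.c2 = np.zeros(n)
        self.c3 = np.zeros(n)
        self.sfa_dec = np.ones(n)
        self.q_sfa = np.zeros(n)
        self.b_cap = np.zeros(n)
        self.refr_steps = np.zeros(n, dtype=np.int32)
        for s in self.spaces:
            exc_p = NEURAL_EXC_PARAMS if s.kind == "neural" else EXC_PARAMS
            for sl, p, refr in ((s.exc_slice, exc_p, s.refr_exc),
                                (s.inh_slice, INH_PARAMS, s.refr_inh)):
                dec = np.exp(-dt / p.tau_m)
                self.vm_dec[sl] = dec
                self.bias_term[sl] = (1 - dec) * p.R_m * p.I_e
                self.c1[sl], self.c2[sl], self.c3[sl] = p.c1, p.c2, p.c3
                self.sfa_dec[sl] = np.exp(-dt / p.tau_sfa)
                self.q_sfa[sl] = p.q_sfa
                self.b_cap[sl] = p.b_sfa_max
                self.refr_steps[sl] = np.maximum(
                    np.round(refr / dt).astype(np.int32), 1)

        # edges (X placeholder ids < 0 resolved to [n_real, n_real+n_x))
        self.groups = list(model.groups)  # snapshot: the model may grow later
        self.group_index = {g.name: i for i, g in enumerate(self.groups)}
        self.n_groups = len(self.groups)
        pre_parts, post_parts, d_parts, w_parts, g_parts = [], [], [], [], []
        for gi, g in enumerate(self.groups):
            pre = g.pre.copy()
            if g.pre_range[0] < 0:  # input population
                pre = pre - g.pre_range[0] + self.n_real
            pre_parts.append(pre)
            post_parts.append(g.post)
            d_parts.append(g.delay_ms)
            w_parts.append(g.w)
            g_parts.append(np.full(len(g), gi, dtype=np.int16))
        pre_all = np.concatenate(pre_parts).astype(np.int32)
        post_all = np.concatenate(post_parts).astype(np.int32)
        d_all = np.concatenate(d_parts)
        w_all = np.concatenate(w_parts)
        grp_all = np.concatenate(g_parts)
        dstep_all = np.maximum(np.round(d_all / dt).astype(np.int32), 1)
        self.ring_len = int(dstep_all.max()) + 1 if len(dstep_all) else 2

        order = np.argsort(pre_all, kind="stable")
        self.e_pre = pre_all[order]
        self.e_post = post_all[order]
        self.e_dstep = dstep_all[order]
        self.e_grp = grp_all[order]
        self.e_w = w_all[order]
        inv = np.empty_like(order)
        inv[order] = np.arange(len(order))
        self.group_eids = []
        start = 0
        for g in self.groups:
            self.group_eids.append(inv[start:start + len(g)].copy())
            start += len(g)
        self.csr_indptr = np.zeros(self.n_real + self.n_x + 1, dtype=np.int64)
        np.add.at(self.csr_indptr, self.e_pre + 1, 1)
        np.cumsum(self.csr_indptr, out=self.csr_indptr)

        # plastic CSC by post
        plastic_eids = np.nonzero(
            np.array([self.groups[g].plastic for g in self.e_grp]))[0]
        order_post = plastic_eids[np.argsort(self.e_post[plastic_eids],
                                             kind="stable")]
        self.pl_eids = order_post.astype(np.int64)
        self.pl_indptr = np.zeros(self.n_real + 1, dtype=np.int64)
        np.add.at(self.pl_indptr, self.e_post[self.pl_eids] + 1, 1)
        np.cumsum(self.pl_indptr, out=self.pl_indptr)

        # group parameter arrays + trace layout
        ng = self.n_groups
        self.g_eta = np.zeros(ng)
        self.g_alpha = np.zeros(ng)
        self.g_Aminus = np.zeros(ng)
        self.g_wmin = np.zeros(ng)
        self.g_wmax = np.zeros(ng)
        self.g_pre_off = np.full(ng, -1, dtype=np.int64)
        self.g_pre_base = np.zeros(ng, dtype=np.int64)
        self.g_pre_size = np.zeros(ng, dtype=np.int64)
        self.g_post_off = np.full(ng, -1, dtype=np.int64)
        self.g_post_base = np.zeros(ng, dtype=np.int64)
        self.g_post_size = np.zeros(ng, dtype=np.int64)
        decs = []
        off = 0
        for gi, g in enumerate(self.groups):
            if not g.plastic:
                continue
            p = g.params
            self.g_eta[gi] = p.eta
            # Sign convention of the anti-causal branch: the engine applies
            # dw = eta * (-alpha) * (exp(-|dt|/tau_minus) - A_minus) for
            # dt < 0, i.e. the tabulated alpha = -1 yields a symmetric
            # coincidence-minus-offset window.  With the branch taken at
            # face value recurrent weights could never potentiate from a
            # silent start (the wider tau_minus window would always win),
            # contradicting the saturated within-assembly weights the
            # model is known to produce; see docs/methods.md.
            self.g_alpha[gi] = -p.alpha
            self.g_Aminus[gi] = p.A_minus
            self.g_wmin[gi] = p.w_min
            self.g_wmax[gi] = p.w_max
            base, size = g.pre_range
            if base < 0:
                base = self.n_real
            self.g_pre_off[gi] = off
            self.g_pre_base[gi] = base
            self.g_pre_size[gi] = size
            decs.append(np.full(size, np.exp(-dt / p.tau_plus)))
            off += size
            if p.alpha != 0.0:
                base, size = g.post_range
                self.g_post_off[gi] = off
                self.g_post_base[gi] = base
                self.g_post_size[gi] = size
                decs.append(np.full(size, np.exp(-dt / p.tau_minus)))
                off += size
        self.trace_dec = (np.concatenate(decs) if decs
                          else np.zeros(0))

    # -- weight persistence --------------------------------------------------

    def pull_weights(self) -> None:
        """Write trained weights back into the model's group arrays."""
        for gi, g in enumerate(self.groups):
            g.w[:] = self.e_w[self.group_eids[gi]]

    def group_weights(self, name: str) -> np.ndarray:
        """Current weights of one group, in the group's edge order."""
        return self.e_w[self.group_eids[self.group_index[name]]]
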