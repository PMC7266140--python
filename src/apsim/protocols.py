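"""Operation protocols: induction, CREATE, LOAD, RECALL, COPY, COMPARE.

Every operation is a disinhibition/stimulus schedule over the simulation
engine:

* **induction** -- repeated pattern presentations to the disinhibited
  content space (each 200 ms pattern + 200 ms idle); afterwards input and
  recurrent content plasticity are frozen, assemblies are identified by
  probing each pattern, and the linear readout is trained on the probe
  responses.
* **CREATE** -- a 1000 ms pattern presentation while one neural space is
  disinhibited; an assembly projection emerges there.
* **LOAD** -- a brief (200 ms) CREATE that reactivates an existing
  projection and refreshes its excitability trace.
* **RECALL** -- the neural space is disinhibited for 200 ms with idle input;
  the content space stays locked for the first 50 ms.  The recently loaded
  projection reignites (its elevated excitability wins the release race)
  and reactivates its content assembly through the trained feedback.
* **COPY** -- a recall from the source space while the destination space is
  disinhibited for the last phase, creating a projection to the recalled
  content there.
* **COMPARE** -- two loads followed by two back-to-back recalls; a readout
  population with depressing synapses from the content space responds to
  the second recall only if the content changed.

Timing constants that the protocol descriptions fix (durations of the
operations and the 5 s load-to-recall delay) are module constants; the
spacing *between* operations is a free choice set to ~3 excitability time
constants so that each trial starts from decayed traces (see
docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .analysis import (LinearDecoder, SimilarityReport, identify_assembly,
                       lowpass, similarity, train_decoder)
from .dynamics import Engine, SpikeRecord
from .network import NetworkModel, component_rng
from .params import DT_MS, TMParams
from .stimuli import PatternSet, make_patterns

INDUCTION_PRESENT_MS = 200.0
INDUCTION_IDLE_MS = 200.0
PROBE_MS = 200.0
CREATE_MS = 1000.0
LOAD_MS = 200.0
RECALL_MS = 200.0
RECALL_C_LOCKED_MS = 50.0
RECALL_DELAY_MS = 5000.0
COPY_PRE_DELAY_MS = 400.0
COPY_DST_OPEN_MS = 100.0
COPY_TEST_DELAY_MS = 400.0
COMPARE_GAP_MS = 50.0
#: the content space is driven by the pattern for this long before the
#: target neural space is disinhibited in CREATE/LOAD, so that the
#: feedforward drive (not residual excitability of previously created
#: assemblies) decides which neurons join the projection.
PRESENT_LEAD_MS = 50.0
#: idle time between operations so excitability traces from the previous
#: operation decay to a fraction of a loaded trace (~3 tau_sfa).
SETTLE_MS = 15000.0


@dataclass
class DisinhibitionSchedule:
    """Explicit (space, t_start, t_end) disinhibition intervals."""

    intervals: list[tuple[str, float, float]] = field(default_factory=list)

    def validate(self, t0: float, t1: float) -> None:
        by_space: dict[str, list[tuple[float, float]]] = {}
        for name, a, b in self.intervals:
            if not (t0 <= a < b <= t1):
                raise ValueError(f"interval {a, b} outside run window")
            by_space.setdefault(name, []).append((a, b))
        for name, iv in by_space.items():
            iv.sort()
            for (a1, b1), (a2, b2) in zip(iv, iv[1:]):
                if a2 < b1:
                    raise ValueError(f"overlapping intervals for {name}")


@dataclass
class OperationResult:
    """Spike record and derived measurements of one protocol operation."""

    name: str
    t_start: float
    t_end: float
    record: SpikeRecord
    active_sets: dict[str, np.ndarray] = field(default_factory=dict)
    similarity: SimilarityReport | None = None
    readout_error: float | None = None


class ProjectionFailure(RuntimeError):
    """An operation failed to activate the expected assembly."""


class AssemblyCircuit:
    """Content space + neural spaces with the full operation repertoire.

    The facade wires patterns, network, engine, and analysis together.
    Typical use::

        circ = AssemblyCircuit(master_seed=1)
        circ.induce()                       # content assemblies + readout
        circ.attach_neural_space("S1")
        for k in range(5):
            circ.create_projection("S1", k)
        circ.settle()
        res = circ.load_delay_recall("S1", 2)
        res.readout_error, res.similarity.passes
    """

    def __init__(self, master_seed: int, n_patterns: int = 5,
                 n_content: int = 1000, n_neural: int = 2000,
                 n_in: int = 200, tables=None, dt: float = DT_MS,
                 pattern_kwargs: dict | None = None):
        self.master_seed = int(master_seed)
        self.model = NetworkModel(master_seed, n_in=n_in, dt=dt,
                                  **({"tables": tables} if tables else {}))
        self.model.add_content_space(n_exc=n_content)
        self.n_neural = n_neural
        self.patterns: PatternSet = make_patterns(
            n_patterns, component_rng(master_seed, "patterns"),
            n_in=n_in, **(pattern_kwargs or {}))
        self.assemblies: list[np.ndarray] | None = None
        self.s_assemblies: dict[str, dict[int, np.ndarray]] = {}
        self.decoder: LinearDecoder | None = None
        self._stage = 0
        self._remake_engine()

    # -- engine lifecycle ---------------------------------------------------

    def _remake_engine(self) -> None:
        """(Re)compile the model and build a fresh engine.

        Trained weights persist in the model; dynamic state restarts, which
        is safe between operations (all memory that matters is synaptic or
        re-established by the next operation).
        """
        if getattr(self, "engine", None) is not None:
            self.engine.net.pull_weights()
            frozen = set(self.engine.frozen)
        else:
            frozen = set()
        self.net = self.model.compile()
        self._stage += 1
        self.engine = Engine(self.net, seed=(self.master_seed * 1000003
                                             + self._stage) & 0x7FFFFFFF)
        self.engine.frozen = frozen
        self.engine.set_lock(self.model.content.name, False)

    engine: Engine | None = None

    @property
    def content_name(self) -> str:
        return self.model.content.name

    def attach_neural_space(self, name: str) -> None:
        """Add a (fresh, randomly wired) neural space to the circuit."""
        self.model.add_neural_space(name, n_exc=self.n_neural)
        self._remake_engine()

    def settle(self, duration_ms: float = SETTLE_MS) -> None:
        """Idle with all neural spaces locked (traces decay)."""
        for s in self.model.neural_spaces:
            self.engine.set_lock(s.name, True)
        self.engine.advance(duration_ms, self.patterns.idle_rates())
        self.engine.drop_record()

    # -- induction ----------------------------------------------------------

    def induce(self, n_presentations: int = 200,
               train_readout: bool = True) -> OperationResult:
        """Form content assemblies by repeated pattern presentations.

        Presentations draw patterns uniformly at random.  Afterwards the
        input and recurrent plasticity of the content space are frozen,
        each pattern is probed once for 200 ms, assemblies are identified
        (>50 Hz in the probe's second half) and the linear readout is
        trained on the probe traces.
        """
        eng = self.engine
        rng = component_rng(self.master_seed, "induction-order")
        idle = self.patterns.idle_rates()
        t0 = eng.t_ms
        for k in rng.integers(0, len(self.patterns), size=n_presentations):
            eng.advance(INDUCTION_PRESENT_MS, self.patterns[int(k)].rates())
            eng.advance(INDUCTION_IDLE_MS, idle)
        eng.drop_record()
        eng.freeze_group(f"X->{self.content_name}")
        eng.freeze_group(f"{self.content_name}.E->E")

        pop = f"{self.content_name}.E"
        self.assemblies = []
        traces, labels = [], []
        for k in range(len(self.patterns)):
            ts = eng.t_ms
            eng.advance(PROBE_MS, self.patterns[k].rates())
            rec = eng.record()
            asm = identify_assembly(rec, pop, ts + PROBE_MS / 2, ts + PROBE_MS)
            if len(asm) == 0:
                raise ProjectionFailure(
                    f"induction failed: empty assembly for pattern {k}")
            self.assemblies.append(asm)
            if train_readout:
                # include the ignition ramp so the readout also handles
                # low-amplitude rising traces (as at the start of a recall)
                grid = np.arange(ts + 10.0, ts + PROBE_MS, 1.0)
                traces.append(lowpass(rec, pop, grid))
                labels.append(k)
            eng.advance(INDUCTION_IDLE_MS, idle)
        if train_readout:
            self.decoder = train_decoder(traces, labels)
        rec = eng.record()
        eng.drop_record()
        return OperationResult(
            name="induce", t_start=t0, t_end=eng.t_ms, record=rec,
            active_sets={pop: np.concatenate(self.assemblies)})

    # -- operations ---------------------------------------------------------

    def _present(self, space: str, pattern_id: int, duration: float,
                 name: str) -> OperationResult:
        eng = self.engine
        for s in self.model.neural_spaces:
            eng.set_lock(s.name, True)
        ts = eng.t_ms
        eng.advance(PRESENT_LEAD_MS, self.patterns[pattern_id].rates())
        eng.set_lock(space, False)
        eng.advance(duration - PRESENT_LEAD_MS,
                    self.patterns[pattern_id].rates())
        eng.set_lock(space, True)
        rec = eng.record(ts, eng.t_ms)
        asm = identify_assembly(rec, f"{space}.E", ts + duration / 2,
                                ts + duration)
        if len(asm) == 0:
            raise ProjectionFailure(f"{name} failed: no assembly in {space}")
        self.s_assemblies.setdefault(space, {})[pattern_id] = asm
        eng.drop_record()
        return OperationResult(name=name, t_start=ts, t_end=eng.t_ms,
                               record=rec, active_sets={f"{space}.E": asm})

    def create_projection(self, space: str, pattern_id: int,
                          duration: float = CREATE_MS) -> OperationResult:
        """Attach the content of ``pattern_id`` to ``space`` (CREATE)."""
        return self._present(space, pattern_id, duration, "create")

    def load(self, space: str, pattern_id: int,
             duration: float = LOAD_MS) -> OperationResult:
        """Briefly reactivate an existing projection (LOAD)."""
        if self.s_assemblies.get(space, {}).get(pattern_id) is None:
            raise ProjectionFailure(
                f"no projection for pattern {pattern_id} in {space}")
        return self._present(space, pattern_id, duration, "load")

    def recall(self, space: str, reference_id: int | None = None,
               keep_open: tuple[str, ...] = ()) -> OperationResult:
        """Retrieve the most recently loaded content of ``space`` (RECALL).

        The space is disinhibited for 200 ms under idle input; the content
        space stays locked for the first 50 ms.  If ``reference_id`` is
        given, the similarity report and per-sample readout error against
        that pattern are attached to the result.
        """
        eng = self.engine
        idle = self.patterns.idle_rates()
        for s in self.model.neural_spaces:
            eng.set_lock(s.name, s.name not in (space, *keep_open))
        eng.set_lock(self.content_name, True)
        ts = eng.t_ms
        eng.advance(RECALL_C_LOCKED_MS, idle)
        eng.set_lock(self.content_name, False)
        eng.advance(RECALL_MS - RECALL_C_LOCKED_MS, idle)
        rec = eng.record(ts, eng.t_ms)
        pop = f"{self.content_name}.E"
        active = identify_assembly(rec, pop, ts + RECALL_MS / 2, ts + RECALL_MS)
        res = OperationResult(name="recall", t_start=ts, t_end=eng.t_ms,
                              record=rec, active_sets={pop: active})
        if reference_id is not None:
            if self.assemblies is None:
                raise ProjectionFailure("no induced assemblies to compare to")
            res.similarity = similarity(self.assemblies[reference_id], active)
            if self.decoder is not None:
                grid = np.arange(ts + RECALL_C_LOCKED_MS, ts + RECALL_MS, 1.0)
                res.readout_error = self.decoder.error(
                    lowpass(rec, pop, grid), reference_id)
        if space not in keep_open:
            eng.set_lock(space, True)
        return res

    def load_delay_recall(self, space: str, pattern_id: int,
                          delay_ms: float = RECALL_DELAY_MS) -> OperationResult:
        """The standard recall trial: LOAD, delay (spaces locked), RECALL."""
        self.load(space, pattern_id)
        self.engine.advance(delay_ms, self.patterns.idle_rates())
        self.engine.drop_record()
        return self.recall(space, reference_id=pattern_id)

    def copy(self, src: str, dst: str, pattern_id: int,
             test: bool = True) -> OperationResult:
        """COPY the content bound to ``src`` into ``dst``.

        Load into src, brief delay, recall from src; towards the end of the
        recall the destination space is additionally disinhibited for
        100 ms, creating a projection to the recalled content there.  The
        copy is verified by a recall from dst 400 ms later.
        """
        eng = self.engine
        idle = self.patterns.idle_rates()
        self.load(src, pattern_id)
        eng.advance(COPY_PRE_DELAY_MS, idle)
        eng.drop_record()
        # recall from src...
        for s in self.model.neural_spaces:
            eng.set_lock(s.name, s.name != src)
        eng.set_lock(self.content_name, True)
        ts = eng.t_ms
        eng.advance(RECALL_C_LOCKED_MS, idle)
        eng.set_lock(self.content_name, False)
        eng.advance(RECALL_MS - RECALL_C_LOCKED_MS, idle)
        # ...then additionally open the destination
        eng.set_lock(dst, False)
        eng.advance(COPY_DST_OPEN_MS, idle)
        rec = eng.record(ts, eng.t_ms)
        asm = identify_assembly(rec, f"{dst}.E", ts + RECALL_MS,
                                ts + RECALL_MS + COPY_DST_OPEN_MS)
        eng.set_lock(src, True)
        eng.set_lock(dst, True)
        eng.drop_record()
        if len(asm) == 0:
            raise ProjectionFailure(f"copy failed: no assembly formed in {dst}")
        self.s_assemblies.setdefault(dst, {})[pattern_id] = asm
        if not test:
            return OperationResult(name="copy", t_start=ts, t_end=eng.t_ms,
                                   record=rec, active_sets={f"{dst}.E": asm})
        eng.advance(COPY_TEST_DELAY_MS, idle)
        eng.drop_record()
        res = self.recall(dst, reference_id=pattern_id)
        res.name = "copy"
        return res

    def compare(self, space_a: str, space_b: str, pattern_a: int,
                pattern_b: int, readout: "CompareReadout") -> dict:
        """COMPARE the contents bound to two spaces.

        Loads ``pattern_a`` into ``space_a`` and ``pattern_b`` into
        ``space_b`` (200 ms each, 50 ms idle after each), then recalls both
        in sequence (2 x 200 ms, no delay).  Returns the readout activity
        of both recall phases and their peak population traces.
        """
        eng = self.engine
        idle = self.patterns.idle_rates()
        self.load(space_a, pattern_a)
        eng.advance(COMPARE_GAP_MS, idle)
        self.load(space_b, pattern_b)
        eng.advance(COMPARE_GAP_MS, idle)
        eng.drop_record()
        ts = eng.t_ms
        for space in (space_a, space_b):
            for s in self.model.neural_spaces:
                eng.set_lock(s.name, s.name != space)
            eng.set_lock(self.content_name, True)
            eng.advance(RECALL_C_LOCKED_MS, idle)
            eng.set_lock(self.content_name, False)
            eng.advance(RECALL_MS - RECALL_C_LOCKED_MS, idle)
        for s in self.model.neural_spaces:
            eng.set_lock(s.name, True)
        rec = eng.record(ts, eng.t_ms)
        eng.drop_record()
        out = readout.respond(rec, f"{self.content_name}.E", ts,
                              ts + 2 * RECALL_MS)
        out["same"] = pattern_a == pattern_b
        return out


class CompareReadout:
    """Readout assembly with depressing synapses from the content space.

    50 leaky integrate-and-fire neurons (rest -60 mV, threshold -20 mV,
    tau_m 20 ms, 5 ms refractory clamp at rest) receive sparse (p = 0.1)
    connections from the content space's excitatory pool through
    short-term-depressing synapses.  After a first recall has depressed the
    synapses of the active content assembly, a second recall of the *same*
    content evokes almost no response, while a different content drives the
    readout as strongly as the first.
    """

    V_REST = -60.0
    V_THRESH = -20.0
    TAU_M = 20.0
    REFR_MS = 5.0
    N_NEURONS = 50
    P_CONN = 0.1

    def __init__(self, n_content: int, master_seed: int,
                 tm: TMParams | None = None, psp_scale: float = 1.0,
                 dt: float = DT_MS):
        self.tm = tm or TMParams()
        self.dt = dt
        self.psp_scale = psp_scale
        rng = component_rng(master_seed, "compare-readout")
        mask = rng.random((n_content, self.N_NEURONS)) < self.P_CONN
        self.syn_pre, self.syn_post = (a.astype(np.int64)
                                       for a in np.nonzero(mask))

    def respond(self, rec: SpikeRecord, population: str,
                t0: float, t1: float) -> dict:
        """Drive the readout from content spikes in [t0, t1).

        Returns the integrated population trace of each recall phase
        (first/second half of the window) and the full 1 ms trace.
        """
        from .analysis import lowpass as _lp  # local to avoid cycle at import

        idx, times = rec.for_population(population)
        m = (times >= t0) & (times < t1)
        idx, times = idx[m], times[m] - t0
        n_steps = int(round((t1 - t0) / self.dt))
        # per-synapse event list with short-term depression efficacies
        order = np.lexsort((times,))
        idx, times = idx[order], times[order]
        ev_steps, ev_syn, ev_w = [], [], []
        # group content spikes per neuron, then expand per synapse
        from .plasticity import tm_efficacy
        by_pre: dict[int, np.ndarray] = {}
        for i in np.unique(idx):
            by_pre[i] = times[idx == i]
        syn_by_pre: dict[int, list[int]] = {}
        for s, p in enumerate(self.syn_pre):
            syn_by_pre.setdefault(int(p), []).append(s)
        for i, ts_i in by_pre.items():
            if i not in syn_by_pre:
                continue
            eff = tm_efficacy(ts_i, self.tm)
            steps = np.minimum((ts_i / self.dt).astype(np.int64),
                               n_steps - 1)
            for s in syn_by_pre[i]:
                ev_steps.append(steps)
                ev_syn.append(np.full(len(steps), s, dtype=np.int64))
                ev_w.append(self.psp_scale * self.tm.w * eff)
        if ev_steps:
            steps = np.concatenate(ev_steps)
            syn = np.concatenate(ev_syn)
            w = np.concatenate(ev_w)
            order = np.argsort(steps, kind="stable")
            ids, spk_steps = _kernels.lif_readout(
                steps[order], syn[order], w[order], n_steps, self.dt,
                self.TAU_M, self.V_REST, self.V_THRESH,
                int(round(self.REFR_MS / self.dt)), self.N_NEURONS,
                self.syn_post)
        else:
            ids = np.empty(0, dtype=np.int32)
            spk_steps = np.empty(0, dtype=np.int64)
        rrec = SpikeRecord(ids.astype(np.int32), (spk_steps + 1) * self.dt,
                           {"readout": (0, self.N_NEURONS)})
        grid = np.arange(1.0, t1 - t0 + 0.5, 1.0)
        tr = _lp(rrec, "readout", grid).sum(axis=1)
        half = len(grid) // 2
        return {"trace": tr,
                "phase1": float(tr[:half].sum()),
                "phase2": float(tr[half:].sum()),
                "spikes": rrec}
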