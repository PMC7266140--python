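"""Reproducible experiment suites over the operation protocols.

Each suite builds its circuits from a master seed, runs the corresponding
protocol, and returns tidy per-trial records (pandas DataFrames) from which
all summary statistics are recomputable.  Desk-scale parameters (instances,
trials, induction length) are arguments with defaults chosen to finish on a
single CPU in minutes; the full-scale settings of the original study are
reached by raising them (5 content instances x 10 neural-space seeds,
200-presentation induction).
"""

from __future__ import annotations

import itertools
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .analysis import VoxelPartition, train_decoder, lowpass, voxelize
from .calibration import RobustnessConfig, perturb
from .network import component_rng
from .params import DEFAULT_TABLES, ConnectionTables
from .protocols import (AssemblyCircuit, CompareReadout, ProjectionFailure,
                        RECALL_C_LOCKED_MS, RECALL_MS)


@dataclass
class ExperimentConfig:
    """Validated configuration of a named suite."""

    experiment: str
    master_seed: int
    n_patterns: int = 5
    n_presentations: int = 200
    n_instances: int = 1
    n_space_seeds: int = 2
    n_trials_per_pattern: int = 1
    delay_ms: float = 5000.0
    sigma_param: float = 0.2
    n_samples: int = 10
    concept_counts: tuple[int, ...] = (5, 30, 35, 40)

    KNOWN = ("recall", "copy", "compare", "roles", "robustness", "capacity")

    def __post_init__(self):
        if self.experiment not in self.KNOWN:
            raise ValueError(f"unknown experiment {self.experiment!r};"
                             f" expected one of {self.KNOWN}")
        if min(self.n_patterns, self.n_presentations, self.n_instances) < 1:
            raise ValueError("counts must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


def build_trained_circuit(master_seed: int, n_patterns: int = 5,
                          n_presentations: int = 200,
                          tables: ConnectionTables | None = None,
                          pattern_kwargs: dict | None = None
                          ) -> AssemblyCircuit:
    """Content-space circuit with induced assemblies and trained readout."""
    circ = AssemblyCircuit(master_seed, n_patterns=n_patterns, tables=tables,
                           pattern_kwargs=pattern_kwargs)
    circ.induce(n_presentations=n_presentations)
    return circ


def prepare_space(circ: AssemblyCircuit, name: str) -> None:
    """Attach a neural space and create projections for every pattern.

    A space that already exists with projections is left untouched.
    """
    have = [s.name for s in circ.model.neural_spaces]
    if name in have and circ.s_assemblies.get(name):
        return
    if name not in have:
        circ.attach_neural_space(name)
    for k in range(len(circ.patterns)):
        circ.create_projection(name, k)
    circ.settle()


def recall_suite(master_seed: int, n_instances: int = 1,
                 n_space_seeds: int = 2, n_patterns: int = 5,
                 n_presentations: int = 200, delay_ms: float = 5000.0,
                 tables: ConnectionTables | None = None,
                 circuit: AssemblyCircuit | None = None) -> pd.DataFrame:
    """LOAD/delay/RECALL trials over instances x neural-space seeds x patterns.

    Returns one row per trial with the readout error and the similarity
    verdict.  A pre-built circuit may be passed to reuse an induction
    (single-instance suites only).
    """
    rows = []
    for inst in range(n_instances):
        if circuit is not None and inst == 0:
            circ = circuit
        else:
            circ = build_trained_circuit(master_seed + inst, n_patterns,
                                         n_presentations, tables)
        for j in range(n_space_seeds):
            name = f"S{j + 1}"
            _prepare_space(circ, name)
            for k in range(n_patterns):
                try:
                    res = circ.load_delay_recall(name, k, delay_ms=delay_ms)
                    rows.append(dict(
                        instance=inst, space_seed=j, pattern=k,
                        readout_error=res.readout_error,
                        retained=res.similarity.retained_fraction,
                        excess=res.similarity.excess_count,
                        passes=res.similarity.passes, failed=False))
                except ProjectionFailure:
                    rows.append(dict(instance=inst, space_seed=j, pattern=k,
                                     readout_error=1.0, retained=0.0,
                                     excess=0, passes=False, failed=True))
                circ.settle(10000.0)
    return pd.DataFrame(rows)


def copy_suite(master_seed: int, n_copies: int = 10, n_patterns: int = 5,
               n_presentations: int = 200, settle_ms: float = 8000.0,
               circuit: AssemblyCircuit | None = None) -> pd.DataFrame:
    """COPY trials S1 -> S2 cycling through the patterns.

    Between trials the circuit idles for ``settle_ms``; a load re-charges
    the excitability trace fully, so shorter gaps suffice here than
    between recall trials.
    """
    circ = circuit or build_trained_circuit(master_seed, n_patterns,
                                            n_presentations)
    _prepare_space(circ, "S1")
    _prepare_space(circ, "S2")
    rows = []
    for t in range(n_copies):
        k = t % n_patterns
        try:
            res = circ.copy("S1", "S2", k)
            rows.append(dict(trial=t, pattern=k,
                             readout_error=res.readout_error,
                             retained=res.similarity.retained_fraction,
                             excess=res.similarity.excess_count,
                             passes=res.similarity.passes, failed=False))
        except ProjectionFailure:
            rows.append(dict(trial=t, pattern=k, readout_error=1.0,
                             retained=0.0, excess=0, passes=False,
                             failed=True))
        circ.settle(settle_ms)
    return pd.DataFrame(rows)


def compare_suite(master_seed: int, n_patterns: int = 5,
                  n_presentations: int = 200, settle_ms: float = 8000.0,
                  circuit: AssemblyCircuit | None = None) -> pd.DataFrame:
    """All n x n content assignments to (S1, S2) through the COMPARE readout.

    Returns per-case first/second-phase readout activity; the decision
    threshold is the log-midpoint between the same/different clusters of
    the second phase (stored in the frame's ``attrs``).
    """
    circ = circuit or build_trained_circuit(master_seed, n_patterns,
                                            n_presentations)
    _prepare_space(circ, "S1")
    _prepare_space(circ, "S2")
    readout = CompareReadout(circ.model.content.n_exc, master_seed)
    rows = []
    for a, b in itertools.product(range(n_patterns), repeat=2):
        out = circ.compare("S1", "S2", a, b, readout)
        rows.append(dict(pattern_a=a, pattern_b=b, same=out["same"],
                         phase1=out["phase1"], phase2=out["phase2"]))
        circ.settle(settle_ms)
    df = pd.DataFrame(rows)
    same = df.loc[df.same, "phase2"].to_numpy()
    diff = df.loc[~df.same, "phase2"].to_numpy()
    floor = max(1e-3, 0.1 * min(x for x in np.concatenate([same, diff])
                                if x > 0) if (df.phase2 > 0).any() else 1e-3)
    theta = float(np.exp(0.5 * (np.log(np.maximum(same, floor)).max()
                                + np.log(np.maximum(diff, floor)).min())))
    df.attrs["theta_cmp"] = theta
    df.attrs["separable"] = bool(same.max() < diff.min())
    return df


# -- roles experiment --------------------------------------------------------

SENTENCES_MEANING = (
    # (class, ((space, item), (space, item))) in presentation order
    (0, (("agent", 0), ("patient", 1))),    # truck hit ball
    (0, (("patient", 1), ("agent", 0))),    # ball was hit by truck
    (1, (("patient", 0), ("agent", 1))),    # truck was hit by ball
    (1, (("agent", 1), ("patient", 0))),    # ball hit truck
)


def _present_sentence(circ: AssemblyCircuit, words, partitions, noise_rng,
                      noise_var: float = 5.0, collect_traces: bool = False):
    """Present a two-word sentence; return per-space voxel signals.

    Words run 200 ms each, back to back, with the word's role space
    disinhibited; the first 50 ms of each word are discarded.
    """
    sigs, traces = {}, {}
    for space, item in words:
        res = circ.load(space, item)
        t0 = res.t_start
        grid = np.arange(t0 + 50.0, t0 + 200.0, 1.0)
        for pop in list(partitions):
            tr = lowpass(res.record, pop, grid)
            sigs.setdefault(pop, []).append(
                voxelize(tr, partitions[pop], noise_rng, noise_var))
            if collect_traces and pop == f"{space}.E":
                traces[(space, item)] = tr
    out = {pop: np.concatenate(v) for pop, v in sigs.items()}
    return (out, traces) if collect_traces else out


def roles_sentence_experiment(master_seed: int, n_presentations: int = 200,
                              noise_var: float = 5.0,
                              circuit: AssemblyCircuit | None = None,
                              agent: str = "agent",
                              patient: str = "patient") -> dict:
    """Decode sentence meaning from fMRI-like voxel signals.

    Two neural spaces (agent and patient roles) carry projections for all
    items; four two-word sentences over the items "truck"/"ball" are shown
    twice.  A linear classifier on the concatenated 5-voxel signals of the
    two role spaces is trained on the first pass and tested on the second;
    a control classifier uses the content space's voxels instead.
    """
    circ = circuit or build_trained_circuit(master_seed, 5, n_presentations)
    for name in (agent, patient):
        _prepare_space(circ, name)
    part_rng = component_rng(master_seed, "voxel-partitions")
    partitions = {
        f"{agent}.E": VoxelPartition.draw(circ.model.space(agent).n_exc, 5,
                                          part_rng),
        f"{patient}.E": VoxelPartition.draw(circ.model.space(patient).n_exc,
                                            5, part_rng),
        f"{circ.content_name}.E": VoxelPartition.draw(
            circ.model.content.n_exc, 5, part_rng),
    }
    noise_rng = component_rng(master_seed, "voxel-noise")
    role_of = {"agent": agent, "patient": patient}
    Xs, Xc, y = [], [], []
    for rep in range(2):
        for cls, words in SENTENCES_MEANING:
            words = tuple((role_of[r], item) for r, item in words)
            sig = _present_sentence(circ, words, partitions, noise_rng,
                                    noise_var)
            Xs.append(np.concatenate([sig[f"{agent}.E"],
                                      sig[f"{patient}.E"]]))
            Xc.append(sig[f"{circ.content_name}.E"])
            y.append(cls)
            circ.settle(2000.0)
    Xs, Xc, y = np.array(Xs), np.array(Xc), np.array(y)
    n = len(SENTENCES_MEANING)
    out = {}
    for nm, X in (("neural", Xs), ("content", Xc)):
        dec = train_decoder([X[i][None, :] for i in range(n)], y[:n])
        out[f"{nm}_error"] = float(np.mean(
            dec.classify(X[n:]) != y[n:]))
    out["n_test"] = n
    return out


def roles_identity_experiment(master_seed: int, n_presentations: int = 200,
                              n_items: int = 5,
                              circuit: AssemblyCircuit | None = None) -> dict:
    """Decode agent and patient identity from their role spaces.

    All 40 orderings of two distinct items bound to the two role spaces are
    presented; half are held out such that no test sentence's item pair
    occurred in any training sentence.  Identity decoders classify 1 ms
    samples of the role space's filtered activity during its word window.
    """
    circ = circuit or build_trained_circuit(master_seed, n_items,
                                            n_presentations)
    for name in ("agent", "patient"):
        if name not in [s.name for s in circ.model.neural_spaces]:
            _prepare_space(circ, name)
    pairs = list(itertools.combinations(range(n_items), 2))
    rng = component_rng(master_seed, "roles-split")
    test_pairs = set(map(tuple, rng.permutation(pairs)[:len(pairs) // 2]
                         .tolist()))
    sentences = []
    for i, j in itertools.permutations(range(n_items), 2):
        for first_role in ("agent", "patient"):
            second = "patient" if first_role == "agent" else "agent"
            words = ((first_role, i), (second, j))
            sentences.append(words)
    samples = {"agent": [], "patient": []}
    for words in sentences:
        recs = {}
        for space, item in words:
            res = circ.load(space, item)
            recs[space] = (res.t_start, item, res.record)
        pair = tuple(sorted(item for _, item in words))
        split = "test" if pair in test_pairs else "train"
        for space, (t0, item, rec) in recs.items():
            grid = np.arange(t0 + 50.0, t0 + 200.0, 1.0)
            tr = lowpass(rec, f"{space}.E", grid)
            samples[space].append((split, item, tr))
        circ.settle(2000.0)
    out = {}
    for space in ("agent", "patient"):
        train = [(t, l) for s, l, t in samples[space] if s == "train"]
        test = [(t, l) for s, l, t in samples[space] if s == "test"]
        dec = train_decoder([t for t, _ in train], [l for _, l in train])
        errs = [dec.error(t, l) for t, l in test]
        out[f"{space}_error"] = float(np.mean(errs))
        out[f"{space}_n_test"] = len(test)
    return out


def robustness_suite(master_seed: int, sigma_param: float = 0.2,
                     n_samples: int = 10, n_presentations: int = 25,
                     n_patterns: int = 5, trials_per_sample: int = 2,
                     delay_ms: float = 5000.0) -> pd.DataFrame:
    """Perturb the plasticity parameters and re-run the recall protocol.

    Each sample redraws the 20 perturbable parameters from
    Normal(v, (sigma*v)^2) (with the documented clipping), rebuilds and
    re-trains a circuit, and runs recall trials.
    """
    rows = []
    rng = component_rng(master_seed, "robustness")
    for s in range(n_samples):
        tables = perturb(DEFAULT_TABLES, sigma_param, rng)
        try:
            circ = build_trained_circuit(master_seed + 7919 * (s + 1),
                                         n_patterns, n_presentations, tables)
            _prepare_space(circ, "S1")
        except ProjectionFailure:
            for k in range(trials_per_sample):
                rows.append(dict(sample=s, trial=k, readout_error=1.0,
                                 passes=False, failed=True))
            continue
        for t in range(trials_per_sample):
            k = t % n_patterns
            try:
                res = circ.load_delay_recall("S1", k, delay_ms=delay_ms)
                rows.append(dict(sample=s, trial=t,
                                 readout_error=res.readout_error,
                                 passes=res.similarity.passes, failed=False))
            except ProjectionFailure:
                rows.append(dict(sample=s, trial=t, readout_error=1.0,
                                 passes=False, failed=True))
            circ.settle(10000.0)
    return pd.DataFrame(rows)


def capacity_suite(master_seed: int, concept_counts=(5, 30),
                   n_presentations_per_concept: int = 5,
                   trials_per_count: int = 5,
                   delay_ms: float = 5000.0) -> pd.DataFrame:
    """Recall performance as the number of stored concepts grows.

    Induction length scales with the number of concepts (a fixed average
    number of presentations per pattern); recall is tested on a sample of
    the concepts through one neural space.
    """
    rows = []
    for n_concepts in concept_counts:
        circ = AssemblyCircuit(master_seed, n_patterns=n_concepts)
        try:
            circ.induce(n_presentations=n_concepts
                        * n_presentations_per_concept)
        except ProjectionFailure:
            rows.append(dict(n_concepts=n_concepts, trial=-1,
                             readout_error=1.0, assembly_size=0,
                             passes=False, failed=True))
            continue
        sizes = [len(a) for a in circ.assemblies]
        circ.attach_neural_space("S1")
        probe = np.linspace(0, n_concepts - 1, trials_per_count).astype(int)
        for k in probe:
            circ.create_projection("S1", int(k))
        circ.settle()
        for t, k in enumerate(probe):
            try:
                res = circ.load_delay_recall("S1", int(k), delay_ms=delay_ms)
                rows.append(dict(n_concepts=n_concepts, trial=t,
                                 readout_error=res.readout_error,
                                 assembly_size=int(np.mean(sizes)),
                                 passes=res.similarity.passes, failed=False))
            except ProjectionFailure:
                rows.append(dict(n_concepts=n_concepts, trial=t,
                                 readout_error=1.0,
                                 assembly_size=int(np.mean(sizes)),
                                 passes=False, failed=True))
            circ.settle(10000.0)
    return pd.DataFrame(rows)


#: backwards-compatible alias
_prepare_space = prepare_space
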