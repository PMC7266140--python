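"""Shared fixtures: small networks for unit tests, one trained circuit.

The session-scoped circuit runs the full induction and projection pipeline
once; acceptance-style tests read assemblies, weights and rates from it and
run their own trials on top.
"""

import numpy as np
import pytest

import apsim
from apsim.experiments import _prepare_space
from apsim.protocols import AssemblyCircuit


@pytest.fixture(scope="session")
def trained():
    """Fully induced circuit with projections in two neural spaces.

    Collects measurements taken at well-defined points of the build into
    ``trained.meta``.
    """
    circ = AssemblyCircuit(master_seed=11)
    meta = {}
    circ.induce(n_presentations=200)
    eng = circ.engine
    t0 = eng.t_ms
    eng.advance(3000.0, circ.patterns.idle_rates())
    meta["spont_content_only"] = eng.record().mean_rate(
        "C.E", t0 + 500.0, t0 + 3000.0)
    eng.drop_record()
    _prepare_space(circ, "S1")
    _prepare_space(circ, "S2")
    # settled spontaneous rate of one disinhibited neural space with the
    # content space locked (the space's own activity, projections in place)
    circ.engine.set_lock(circ.content_name, True)
    circ.engine.set_lock("S1", False)
    t0 = circ.engine.t_ms
    circ.engine.advance(2500.0, circ.patterns.idle_rates())
    meta["spont_S"] = circ.engine.record().mean_rate(
        "S1.E", t0 + 500.0, t0 + 2500.0)
    circ.engine.set_lock(circ.content_name, False)
    circ.engine.drop_record()
    circ.settle()
    circ.meta = meta
    return circ


@pytest.fixture()
def tiny_engine_factory():
    """Small content-space network for fast dynamics tests."""

    def make(seed=3, n_exc=200, n_in=40):
        m = apsim.NetworkModel(seed, n_in=n_in)
        m.add_content_space(n_exc=n_exc)
        return apsim.Engine(m.compile(), seed=seed)

    return make
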