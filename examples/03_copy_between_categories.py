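"""COPY the content bound to one structural category into another.

With projections in S1, a content is loaded there, recalled into the
content space, and -- while the recalled assembly is active -- the second
space S2 is disinhibited for 100 ms, creating a projection to the same
content there.  A recall from S2 400 ms later verifies the transfer.
"""

from apsim.experiments import prepare_space
from apsim.protocols import AssemblyCircuit

circ = AssemblyCircuit(master_seed=1)
circ.induce(n_presentations=200)
prepare_space(circ, "S1")
circ.attach_neural_space("S2")
circ.settle()

res = circ.copy("S1", "S2", pattern_id=1)
rep = res.similarity
print(f"copied content 1 from S1 to S2; recall from S2 retained "
      f"{rep.retained_fraction:.2f}, excess {rep.excess_count} "
      f"-> criterion {'met' if rep.passes else 'NOT met'}")
print(f"readout error on the verification recall: "
      f"{100 * res.readout_error:.1f}%")
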