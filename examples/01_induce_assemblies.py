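"""Induce concept assemblies in the content space.

Presents five rate patterns (25 of 200 input neurons at 100 Hz) to the
disinhibited content space 200 times; Hebbian plasticity carves out one
assembly per pattern.  Prints the assembly sizes, the mean recurrent weight
within and between assemblies, and the spontaneous rate afterwards --
within-assembly weights saturate near the 0.6 pA bound while
between-assembly weights are driven to zero, which is what makes each
assembly a stable attractor.
"""

import numpy as np

from apsim.protocols import AssemblyCircuit

circ = AssemblyCircuit(master_seed=1)
circ.induce(n_presentations=200)

sizes = [len(a) for a in circ.assemblies]
print(f"assembly sizes: {sizes}")

net = circ.net
member = np.full(circ.model.content.n_exc, -1)
for i, a in enumerate(circ.assemblies):
    member[a] = i
gi = net.group_index["C.E->E"]
eids = net.group_eids[gi]
pre, post, w = net.e_pre[eids], net.e_post[eids], net.e_w[eids]
within = (member[pre] >= 0) & (member[pre] == member[post])
between = (member[pre] >= 0) & (member[post] >= 0) & ~within
print(f"recurrent weight within assemblies:  {w[within].mean():.3f} pA")
print(f"recurrent weight between assemblies: {w[between].mean():.3f} pA")

t0 = circ.engine.t_ms
circ.engine.advance(3000.0, circ.patterns.idle_rates())
rate = circ.engine.record().mean_rate("C.E", t0 + 500.0, t0 + 3000.0)
print(f"spontaneous rate of the trained content space: {rate:.2f} Hz")
print("(sizes of 50-90, within ~0.6, between ~0, and a few Hz of "
      "spontaneous activity indicate a healthy attractor code)")
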