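# apsim — assembly projections in spiking neural networks

How does a brain attach *structure* to *content* — mark "truck" as the
agent and "ball" as the patient of a sentence — using nothing but generic,
randomly connected circuits?  `apsim` implements the **assembly
projection** model of this computation: a recurrent *content space* C holds
concept assemblies; separate *neural spaces* S₁, S₂, … each stand for one
structural category; and transient disinhibition plus fast Hebbian
plasticity lets an assembly projection — a sparse assembly in a neural
space, bidirectionally linked to a content assembly — be **created**,
**recalled**, **copied**, and **compared** on demand.

The model is built from stochastic point neurons whose hazard is

    ρᵢ(t) = c₁·V′ᵢ(t) + c₂·(exp(c₃·V′ᵢ(t)) − 1),   V′ᵢ = Vᵢ + b_sfa,i

(exponential for excitatory, linear for inhibitory cells), with
leaky-integrator membranes, delta synapses, and pair-based STDP with a
constant negative offset,

    Δw = η·(e^{−Δt/τ₊} − A₋)        for Δt = t_post − t_pre ≥ 0,

on every connection between excitatory neurons.  A per-neuron excitability
trace b_sfa (+0.02 mV per spike, capped at 0.5 mV, τ = 5 s) marks recently
active neurons; it is the short-term memory that lets a disinhibited neural
space reignite its most recently loaded assembly.  Full model details and
the calibration of the two unit-convention constants are in
[docs/methods.md](docs/methods.md).

## Worked example

```python
from apsim.protocols import AssemblyCircuit
from apsim.experiments import prepare_space

circ = AssemblyCircuit(master_seed=1)
circ.induce(n_presentations=200)     # form 5 content assemblies
prepare_space(circ, "S1")           # attach a neural space + CREATE x5
res = circ.load_delay_recall("S1", pattern_id=2)
print(res.similarity, res.readout_error)
```

Running `python examples/02_create_and_recall.py` (which does the above)
prints:

```
projections created for all five contents in S1
recalled content 2: retained 0.96 of 72 assembly neurons, 12 excess
similarity criterion (>=80% retained, <=20% excess): met
readout classification error during the recall: 0.7% of 1 ms samples
```

Reading: five seconds after content 2 was last loaded into S1 — with all
recurrent activity extinguished in between — disinhibiting S1 reactivated
its projection assembly from the excitability trace alone, and the trained
feedback reinstated 96% of the original content assembly; a linear readout
identifies the recalled content from the content-space activity with under
1% sample error.  The other scripts in `examples/` demonstrate induction,
COPY, COMPARE, and the fMRI-style role-binding decoding, one capability
each.

A thin CLI wraps the experiment suites (`apsim run recall|copy|compare|
roles|capacity`, `apsim robustness`, `apsim calibrate`, `apsim
build-network`, `apsim report`); the library API is the primary interface.

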