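# Methods

`apsim` simulates a family of generic spiking networks in which *assembly
projections* attach structural categories (agent, patient, ...) to content
(concepts, words).  This note documents the model, the conventions the
implementation had to fix where the published description is under-
determined, the calibration of those conventions, and the limits of what
the shipped experiments demonstrate.

## Network and neuron model

The network consists of one **content space** C (1000 excitatory, 250
inhibitory neurons), one or more **neural spaces** S (2000 E, 500 I), and an
input population X of 200 Poisson units.  Within every space, excitatory
neurons are recurrently connected with probability 0.1 (plastic), and E/I
pools are coupled by static synapses (E→I p=0.575, I→E p=0.6, I→I p=0.55).
X projects all-to-all onto C's excitatory pool; C and each S are coupled
bidirectionally with p=0.1.  All inter-population wiring is drawn
independently per ordered pair (no symmetry, no self-connections), from
per-component random streams so that adding a space never changes the
realization of existing ones.

Neurons are stochastic point units: the membrane potential decays with
τ_m = 10 ms towards R_m·(I_e + I_inh) and receives instantaneous jumps from
delivered spikes; a neuron fires in a time step of Δt = 0.1 ms with
probability 1 − exp(−ρΔt), where the hazard is

    ρ = c1·V' + c2·(exp(c3·V') − 1),    V' = V + b_sfa

with c1 = 0, c2 = 1000 Hz, c3 = 1/mV for excitatory and c1 = 10 Hz/mV,
c2 = 0 for inhibitory neurons.  After a spike the membrane resets to 0 and
the neuron is refractory for a per-neuron duration drawn once from
Γ(k = 4, mean = 3.5 ms).  Excitatory neurons of neural spaces carry an
**excitability trace** b_sfa that increments by 0.02 mV per spike, is
capped at 0.5 mV, and decays with τ_sfa = 5 s — the short-term memory that
recall relies on.

### Unit conventions (calibrated once)

The published parameter tables label synaptic weights "pA".  Taken
literally (pA × 0.5 MΩ) a spike would deflect the membrane by well under a
microvolt and the network would be inert, so a convention had to be fixed.
`apsim` uses delta synapses: a delivered spike of tabulated weight *w*
produces a voltage jump of `psp_scale · w` millivolts with `psp_scale = 1`
(the convention of delta-synapse point-process simulators).  Under that
reading the static E/I weights (17.39 / −4.76 / −16.67) would produce
17 mV unitary jumps and a fluctuation-dominated inhibitory loop that
quenches all but a handful of neurons, so the static pathways carry an
additional scale, calibrated once per space kind against the model's own
published behaviour — content assemblies of 50–90 neurons, within-assembly
recurrent weights ≈ 0.59 pA, spontaneous rates of a few Hz, and reliable
recall:

    STATIC_SCALE_CONTENT = 0.065      STATIC_SCALE_NEURAL = 0.06

The resulting unitary PSPs (E→I ≈ 1.1 mV, I→E ≈ −0.3 mV) are in the range
of the cortical measurements the table is based on.  These two constants
and the lock realization below are the only calibrated quantities; all
tabulated parameters are used verbatim.

### The inhibitory lock

A space is silenced by an "inhibitory lock" (nominally a −4 nA current,
i.e. a −2 mV membrane fixed point).  Under the mV-jump convention a −2 mV
current cannot gate tens of mV of trained afferent drive, and a current
deep enough to do so costs a ~50 ms recovery climb that consumes the
recall pre-phase.  The lock is therefore realized as a **clamp**: a locked
neuron neither integrates nor fires (input in flight is discarded, as
during refractoriness), and on disinhibition the membrane resumes from a
release potential of −1 mV.  The release dynamics double as the recall
selection mechanism: neurons whose excitability trace is elevated reach
positive hazard several milliseconds before the rest of the pool, so the
most recently loaded assembly ignites in an exclusive window (~13 ms after
release) and its recurrent avalanche is established before any competitor
crosses threshold.  The release potential is a compromise — too close to
threshold and the diffuse background of the 2000-neuron pool swamps the
biased assembly; at the full −2 mV the single ignition attempt before the
content space opens makes recall timing unreliable.  One asymmetry
matters: when the *content* space is released during a recall, spikes
already in flight from the blasting neural space are kept (its release is
the read-out moment), whereas a neural space discards in-flight input at
release so that stale content-space activity cannot detonate arbitrary
neurons at the release instant.

## Plasticity

All synapses between excitatory neurons are plastic; a pairing of a
presynaptic and a postsynaptic spike with Δt = t_post − t_pre changes the
weight by

    η·(exp(−Δt/τ+) − A−)          Δt ≥ 0
    η·|α|·(exp(−|Δt|/τ−) − A−)    Δt < 0   (absent where α = 0)

with per-connection-type parameters from the shipped table and clipping to
[0, w_max] after every update.  Two bookkeeping conventions are fixed by
the implementation:

* **Offset per triggering spike.**  The exponential term is all-to-all
  (every earlier partner spike contributes through an exponential trace),
  while the constant −A− offset is paid once per triggering spike.  This
  makes the rule self-normalizing: the net drift of a weight is positive
  exactly when the partner's rate exceeds A−/τ, so high-rate co-activation
  potentiates to the bound and background-rate pairing decays to zero —
  which is what produces the saturated within-assembly weights and the
  zero between-assembly weights.  (A per-pairing offset would make the net
  drift scale with an arbitrary pairing-window length and, for any window
  wider than ~τ+, would prevent feedforward potentiation altogether.)
* **Symmetric coincidence window.**  The anti-causal branch enters with
  amplitude |α| and the same coincidence-minus-offset shape.  Taken with a
  literal negative sign, recurrent weights provably could not potentiate
  from their tabulated initial value of zero: the anti-causal window is
  wider than the causal one (τ− > τ+), so symmetric co-activation would
  always net depression, contradicting the saturated recurrent weights the
  trained model is known to have.
* Pairings are evaluated at spike emission times (delays ≤ 10 ms are
  second-order against τ ≥ 20 ms), and updates are applied immediately at
  the triggering spike.

Plasticity is gated by disinhibition: every plastic connection with an
endpoint in a neural space updates only while that space is disinhibited,
and the content space's input and recurrent connections are frozen
permanently once induction ends.

The comparison readout uses short-term depression (standard two-variable
release/recovery dynamics).  The cited synapse class's parameters are not
printed in the source material; the shipped values (U = 0.5,
τ_rec = 700 ms, τ_fac = 20 ms, w = 50) are literature-scale and calibrated
so that a repeated recall of the same content leaves the readout
near-silent.

## Protocols

* **Induction** — 200 presentations (drawn uniformly at random), each
  200 ms of one pattern followed by 200 ms of idle input (all X at
  12.5 Hz); then input/recurrent plasticity is frozen, each pattern is
  probed once for 200 ms, and neurons firing > 50 Hz in the probe's second
  half form that pattern's assembly.  The linear readout (multinomial
  logistic regression, library-default ridge strength) is trained on the
  low-pass-filtered probe responses, including the ignition ramp so it can
  classify low-amplitude rising traces.
* **CREATE** — 1000 ms of one pattern with the target space disinhibited.
  The content space is driven for 50 ms before the space is released, so
  that the winner selection is made by feedforward drive rather than by
  residual excitability of previously created assemblies (without the
  lead-in, all contents collapse onto the first created assembly under the
  clamp-release dynamics).
* **LOAD** — a 200 ms CREATE onto an existing projection.
* **RECALL** — load, 5 s idle delay with all neural spaces locked, then
  200 ms disinhibition of the space with the content space locked for the
  first 50 ms.
* **COPY** — load into the source, 400 ms delay, recall from the source
  with the destination additionally disinhibited for the last 100 ms;
  verified by a recall from the destination 400 ms later.
* **COMPARE** — two loads (200 ms each, 50 ms idle after each), then two
  back-to-back recalls (2 × 200 ms); the verdict thresholds the
  second-phase activity of the depressing-synapse readout at the log-scale
  midpoint between the same/different clusters of a calibration grid.

The published protocols fix the within-operation timing; the spacing
*between* operations is left open and is set here to 15 s after a block of
CREATEs and ~10 s between recall trials (≈ 2–3 τ_sfa), so that each trial
starts from decayed excitability traces.  Recall selection margins are a
ratio of exponentials of trace values, and a competitor assembly re-charged
by a recall only 5 s earlier halves the margin.

## Synthetic data

All inputs are generated: rate patterns activate 25 of 200 input neurons
at 100 Hz (others 0.1 Hz; idle 12.5 Hz everywhere, chosen so the mean input
rate is phase-independent), realized as independent Bernoulli-per-step
trains on the 0.1 ms grid.  For more than 8 patterns, disjoint active sets
are impossible and independent random 25-subsets are drawn.  A reduced-rate
variant (60 / 1 Hz) is available as a preset.  The generator reproduces the
study's input statistics exactly; it does not emulate any structure of
natural stimuli (correlations, timing patterns, rate gradients), so passing
tests say nothing about robustness to naturalistic inputs.

## Problem sizes of the shipped experiments

The packaged suites default to one content-space instance and two
neural-space wirings (10 recall trials), 10 copies, the full 5 × 5 compare
grid, one role-binding instance, and small robustness/capacity samples;
the full-scale study (5 instances × 10 wirings, 100 robustness samples,
40-concept sweeps) is reached by raising the corresponding arguments.
Summary numbers in this repository are produced at the desk scale.

## Known limitations

* The two static-scale constants and the lock realization are calibrated
  against published network-level statistics, not derived; other
  combinations (e.g. a different PSP convention with retuned plasticity
  constants) could reproduce the same targets.
* Spontaneous content-space rates land ~1 Hz below the published 5.5 Hz.
  The neural-space spontaneous rate of 2.6 Hz is not reproduced in any
  state of the calibrated model: with both spaces disinhibited the mutual
  excitation settles around 16-20 Hz (the initial feedback weights make
  that state very sensitive to the neural-space inhibition scale), while
  the space alone (content space locked) idles at ~4 Hz after the traces
  settle.
* Recalled assemblies carry more excess neurons (~5–15) than the published
  0.1 ± 0.5: non-members keep a tonic input advantage from their
  un-depressed input weights, and the winner-take-all margin at recall is
  thinner than at a pattern presentation.  After the 25-presentation
  shortened induction (weak, small assemblies), the 80%/20% similarity
  criterion is usually violated on the excess side even though the readout
  still classifies recalls at ~1% error; the published claim for that
  variant concerns only the readout error.
* A COPY inherits the excess of the recall that seeds it, so copied
  projections are slightly less precise than created ones.
* In a COMPARE, the same-content response of the readout is reduced to
  well under half of the first-phase response and the 25-case grid is
  perfectly threshold-separable, but the response is not *absent*: the
  excess neurons of the second recall arrive with un-depressed synapses.
* The role-binding control decoder (content-space voxels) performs better
  than the published chance level: with the trained feedback in place, the
  open role space perturbs the content assembly through a role-specific
  subset of feedback synapses, and the 5-voxel sums resolve that
  perturbation at the fixed noise variance.  Role information is therefore
  not strictly absent from the simulated content-space signal.
* Readout errors concentrate in the first milliseconds after the content
  space opens, before any spike has arrived at the classifier's filter;
  the ~1% floor is this transition artifact, consistent in magnitude with
  the published 0.9 ± 0.2%.  After the shortened 25-presentation induction
  the error additionally varies strongly across content-space instances
  (1-14%): occasional weakly-imprinted patterns recall incorrectly.
* The role-identity decoders (who is the agent / who is the patient,
  trained and tested on disjoint item pairs over all 40 two-word
  sequences) reach ~40% per-1-ms-sample error against an 80% chance level
  -- role-specific content is clearly decodable from each role space and
  generalizes across partners, but not at the published near-zero error;
  consecutive sentences leave overlapping excitability traces that blur
  the per-sample features.
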