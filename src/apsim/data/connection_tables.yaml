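# Canonical connection parameters of the assembly-projection network.
#
# static: non-plastic connections between the excitatory (E) and inhibitory (I)
#   pools inside every space (content space and neural spaces alike).
# plastic: STDP-equipped connections between excitatory neurons.  Rows are
#   keyed by the space hosting the POSTSYNAPTIC neurons.  delay / w_init given
#   as [lo, hi] are drawn per edge from a uniform distribution; scalars are
#   fixed.  tau_minus: null together with alpha = 0 means the post-before-pre
#   branch of the pairing rule is inactive for that connection type.
# Weights are in the table's pA units; the simulator converts a delivered spike
# of weight w into a membrane-potential jump of psp_scale * w millivolts.
static:
  E->I: {p: 0.575, w: 17.39, delay: 0.5}
  I->E: {p: 0.6,   w: -4.76, delay: 0.5}
  I->I: {p: 0.55,  w: -16.67, delay: 0.5}
plastic:
  content:
    X->E: {p: 1.0, delay: [1.0, 10.0], w_init: [0.0, 0.8],  w_min: 0.0, w_max: 0.8,
           alpha: 0.0, tau_plus: 25.0, tau_minus: null, A_minus: 0.4, eta: 0.01}
    S->E: {p: 0.1, delay: [1.0, 10.0], w_init: [0.19, 0.39], w_min: 0.0, w_max: 0.87,
           alpha: 0.0, tau_plus: 20.0, tau_minus: null, A_minus: 0.47, eta: 0.008}
    E->E: {p: 0.1, delay: 1.0, w_init: 0.0, w_min: 0.0, w_max: 0.6,
           alpha: -1.0, tau_plus: 25.0, tau_minus: 40.0, A_minus: 0.5, eta: 0.0025}
  neural:
    C->E: {p: 0.1, delay: [1.0, 10.0], w_init: [0.48, 0.86], w_min: 0.0, w_max: 1.33,
           alpha: 0.0, tau_plus: 21.0, tau_minus: null, A_minus: 0.28, eta: 0.004}
    E->E: {p: 0.1, delay: 1.0, w_init: [0.44, 0.87], w_min: 0.0, w_max: 1.08,
           alpha: -1.0, tau_plus: 37.0, tau_minus: 49.0, A_minus: 0.52, eta: 0.006}
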