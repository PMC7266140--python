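"""Model parameters: neuron constants, connection tables, plasticity rules.

All times are in ms, voltages in mV, rates in Hz unless stated otherwise.
Synaptic weights carry the nominal pA units of the connection tables; a
delivered spike of weight ``w`` produces a membrane-potential jump of
``psp_scale * w`` mV (delta synapses, see :mod:`apsim.dynamics`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import yaml

# Global integration time step (ms).
DT_MS = 0.1

# Inhibitory lock current (nA) as tabulated.  Applied to every neuron of a
# locked space.
I_INH_LOCKED = -4.0

# The lock is implemented as a clamp at its membrane fixed point
# R_m * I_inh = -2 mV: while a space is locked its neurons are held at the
# lock potential (no integration, no spikes -- shunting-style veto), and on
# disinhibition the dynamics resume from -2 mV.  A plain current of -4 nA
# cannot play the lock's role under the delta-jump weight convention: it is
# overridden by tens of mV of trained afferent drive, and any current deep
# enough to gate that drive costs a recovery climb of tens of ms that
# consumes the recall pre-phase.  The clamp keeps both defining properties:
# absolute silence while engaged, release from -2 mV within ~20 ms.  The
# release dynamics implement recall selection: neurons with an elevated
# excitability bias reach positive hazard several ms before the rest of the
# space, so the most recently loaded assembly ignites in an exclusive
# window.
#
# The release potential is a compromise: releasing very close to threshold
# lets the diffuse background of the whole pool swamp the biased assembly
# (selection fails), while releasing from the full -2 mV fixed point delays
# the first ignition attempt to ~20 ms and leaves recalls with a single
# attempt before the content space opens.  -1 mV gives a ~13 ms first
# crossing, preserves the several-ms exclusive window of the biased
# assembly, and makes recall ignition timing reliable.
V_LOCK_CLAMP = -1.0

# Conversion of a tabulated weight into a voltage jump (mV per weight unit).
# The tables print weights in pA; taken literally (pA x MOhm) a spike would
# move the membrane by sub-microvolts, which cannot drive the network.  A
# delivered spike instead acts as a delta pulse that deflects the membrane
# by psp_scale * w millivolts, the convention of delta-synapse point-process
# backends.
PSP_SCALE = 1.0

# Additional scale on the static E<->I weights.  At psp_scale alone the
# static pathways would produce 17 mV unitary jumps and a fluctuation-
# dominated inhibitory loop that quenches all but a handful of winners.
# The static scale is calibrated (once, per space kind since the pool sizes
# differ while the table is shared) so that the trained, disinhibited
# network shows the reported spontaneous rates (content 5.5 Hz, neural
# 2.6 Hz), content assemblies of 50-90 neurons, and a sharp winner-take-all
# (losers < 1 Hz during a presentation).  The resulting unitary PSPs
# (E->I ~1.1-1.6 mV, I->E ~-0.3 to -0.4 mV) are in the physiological range
# of the cortical data behind the table.
STATIC_SCALE_CONTENT = 0.065
STATIC_SCALE_NEURAL = 0.06


@dataclass(frozen=True)
class NeuronParams:
    """Stochastic point neuron with exponential/linear hazard.

    The instantaneous firing rate (hazard, Hz) at effective potential V' is
    ``c1 * V' + c2 * (exp(c3 * V') - 1)``, clipped at zero.  ``q_sfa``,
    ``tau_sfa`` and ``b_sfa_max`` control the per-spike excitability bias;
    the refractory duration is drawn once per neuron from a Gamma
    distribution with shape ``refr_shape``.
    """

    c1: float = 0.0            # Hz/mV
    c2: float = 1000.0         # Hz
    c3: float = 1.0            # 1/mV
    tau_m: float = 10.0        # ms
    R_m: float = 0.5           # MOhm
    I_e: float = 0.2           # nA
    q_sfa: float = 0.0         # mV per spike
    tau_sfa: float = 5000.0    # ms
    b_sfa_max: float = 0.5     # mV
    refr_shape: float = 4.0    # Gamma shape k
    refr_scale_param: float = 3.5  # Gamma mu (ms); meaning set by refr_mu_mode
    # "mean": mu is the mean duration (k * scale = mu); "scale": mu is the
    # Gamma scale parameter (mean = k * mu).
    refr_mu_mode: str = "mean"

    def __post_init__(self):
        if not (self.tau_m > 0 and self.tau_sfa > 0):
            raise ValueError("time constants must be positive")
        if self.q_sfa < 0 or self.b_sfa_max < 0:
            raise ValueError("q_sfa and b_sfa_max must be non-negative")
        if not (self.refr_shape > 0 and self.refr_scale_param > 0):
            raise ValueError("refractory Gamma parameters must be positive")

    @property
    def refr_scale(self) -> float:
        """Gamma scale parameter in ms."""
        if self.refr_mu_mode == "mean":
            return self.refr_scale_param / self.refr_shape
        if self.refr_mu_mode == "scale":
            return self.refr_scale_param
        raise ValueError(f"unknown refr_mu_mode {self.refr_mu_mode!r}")


#: Excitatory neurons: purely exponential hazard.
EXC_PARAMS = NeuronParams(c1=0.0, c2=1000.0, c3=1.0, I_e=0.2)
#: Excitatory neurons of a neural space additionally carry the excitability
#: trace used by RECALL.
NEURAL_EXC_PARAMS = replace(EXC_PARAMS, q_sfa=0.02)
#: Inhibitory neurons: linear hazard, no bias current, no excitability trace.
INH_PARAMS = NeuronParams(c1=10.0, c2=0.0, c3=0.0, I_e=0.0)


@dataclass(frozen=True)
class STDPParams:
    """Pair-based STDP with a constant negative offset.

    A pairing with ``dt = t_post - t_pre`` changes the weight by
    ``eta * (exp(-|dt|/tau_plus) - A_minus)`` for ``dt >= 0`` and by
    ``eta * alpha * (exp(-|dt|/tau_minus) - A_minus)`` for ``dt < 0``.
    Weights are clipped to ``[w_min, w_max]`` after every update.
    """

    eta: float
    alpha: float
    tau_plus: float
    tau_minus: float | None
    A_minus: float
    w_min: float
    w_max: float
    w_init_lo: float
    w_init_hi: float
    delay_lo: float
    delay_hi: float
    p: float = 0.1

    def __post_init__(self):
        if self.tau_plus <= 0:
            raise ValueError("tau_plus must be positive")
        if self.tau_minus is None and self.alpha != 0.0:
            raise ValueError("groups without tau_minus must have alpha = 0")
        if self.w_min > self.w_max:
            raise ValueError("w_min must not exceed w_max")

    def clipped_init_bounds(self) -> tuple[float, float]:
        lo = min(max(self.w_init_lo, self.w_min), self.w_max)
        hi = min(max(self.w_init_hi, self.w_min), self.w_max)
        return lo, max(lo, hi)


@dataclass(frozen=True)
class StaticParams:
    """Non-plastic connection type (single weight and delay)."""

    p: float
    w: float
    delay: float


@dataclass(frozen=True)
class TMParams:
    """Tsodyks-Markram short-term dynamics for the comparison readout.

    Literature-derived stand-in values for the depressing interneuron
    synapse class cited for the readout; the exact published values are not
    printed in the source material, so ``U``/``tau_rec``/``tau_fac`` are
    calibrated so that a repeated recall of the same content yields a
    near-absent readout response.
    """

    U: float = 0.5
    tau_rec: float = 700.0  # ms
    tau_fac: float = 20.0   # ms
    w: float = 50.0         # pA

    def __post_init__(self):
        if not (0 < self.U <= 1):
            raise ValueError("U must be in (0, 1]")
        if self.tau_rec <= 0:
            raise ValueError("tau_rec must be positive")


_REQUIRED_PLASTIC_KEYS = {
    "p", "delay", "w_init", "w_min", "w_max",
    "alpha", "tau_plus", "tau_minus", "A_minus", "eta",
}


def _as_pair(v) -> tuple[float, float]:
    if isinstance(v, (list, tuple)):
        lo, hi = float(v[0]), float(v[1])
    else:
        lo = hi = float(v)
    if hi < lo:
        raise ValueError(f"invalid interval {v!r}")
    return lo, hi


def _parse_plastic(row: dict) -> STDPParams:
    missing = _REQUIRED_PLASTIC_KEYS - set(row)
    if missing:
        raise ValueError(f"plastic table row missing keys: {sorted(missing)}")
    d_lo, d_hi = _as_pair(row["delay"])
    w_lo, w_hi = _as_pair(row["w_init"])
    tau_minus = row["tau_minus"]
    return STDPParams(
        eta=float(row["eta"]), alpha=float(row["alpha"]),
        tau_plus=float(row["tau_plus"]),
        tau_minus=None if tau_minus is None else float(tau_minus),
        A_minus=float(row["A_minus"]),
        w_min=float(row["w_min"]), w_max=float(row["w_max"]),
        w_init_lo=w_lo, w_init_hi=w_hi, delay_lo=d_lo, delay_hi=d_hi,
        p=float(row["p"]),
    )


@dataclass(frozen=True)
class ConnectionTables:
    """Validated static + plastic connection tables."""

    static: dict[str, StaticParams]
    plastic: dict[str, STDPParams]  # keys: "C:X->E", "C:S->E", "C:E->E", "S:C->E", "S:E->E"

    def plastic_row(self, space_kind: str, conn: str) -> STDPParams:
        key = f"{space_kind}:{conn}"
        if key not in self.plastic:
            raise KeyError(f"no plastic connection table row for {key}")
        return self.plastic[key]


def load_tables(path=None) -> ConnectionTables:
    """Load connection tables from YAML (default: the shipped tables)."""
    if path is None:
        text = resources.files("apsim.data").joinpath("connection_tables.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    static = {}
    for name in ("E->I", "I->E", "I->I"):
        row = raw["static"][name]
        static[name] = StaticParams(p=float(row["p"]), w=float(row["w"]),
                                    delay=float(row["delay"]))
    plastic = {}
    for kind, prefix in (("content", "C"), ("neural", "S")):
        for name, row in raw["plastic"][kind].items():
            plastic[f"{prefix}:{name}"] = _parse_plastic(row)
    expected = {"C:X->E", "C:S->E", "C:E->E", "S:C->E", "S:E->E"}
    if set(plastic) != expected:
        raise ValueError(f"plastic table incomplete: {sorted(set(plastic) ^ expected)}")
    return ConnectionTables(static=static, plastic=plastic)


DEFAULT_TABLES = load_tables()


# --- Calibration search space -------------------------------------------------
# The 23 tunable plasticity parameters (the table's optimized entries), and the
# 20-parameter subset perturbed in the robustness harness (all but the three
# alpha values, which set the overall STDP shape).

#: (table key, field name) of every optimized plasticity parameter.
OPTIMIZED_PARAMS: tuple[tuple[str, str], ...] = (
    ("C:S->E", "w_init_lo"), ("C:S->E", "w_init_hi"), ("C:S->E", "w_max"),
    ("C:S->E", "alpha"), ("C:S->E", "tau_plus"), ("C:S->E", "A_minus"), ("C:S->E", "eta"),
    ("C:E->E", "tau_minus"),
    ("S:C->E", "w_init_lo"), ("S:C->E", "w_init_hi"), ("S:C->E", "w_max"),
    ("S:C->E", "alpha"), ("S:C->E", "tau_plus"), ("S:C->E", "A_minus"), ("S:C->E", "eta"),
    ("S:E->E", "w_init_lo"), ("S:E->E", "w_init_hi"), ("S:E->E", "w_max"),
    ("S:E->E", "alpha"), ("S:E->E", "tau_plus"), ("S:E->E", "tau_minus"),
    ("S:E->E", "A_minus"), ("S:E->E", "eta"),
)

#: The robustness harness perturbs all optimized parameters except alphas.
ROBUSTNESS_PARAMS: tuple[tuple[str, str], ...] = tuple(
    (k, f) for (k, f) in OPTIMIZED_PARAMS if f != "alpha"
)


def apply_overrides(tables: ConnectionTables,
                    overrides: dict[tuple[str, str], float]) -> ConnectionTables:
    """Return new tables with ``{(table key, field): value}`` applied."""
    plastic = dict(tables.plastic)
    grouped: dict[str, dict[str, float]] = {}
    for (key, fieldname), value in overrides.items():
        grouped.setdefault(key, {})[fieldname] = float(value)
    for key, kw in grouped.items():
        plastic[key] = replace(plastic[key], **kw)
    return ConnectionTables(static=tables.static, plastic=plastic)


def gamma_refractory_durations(n: int, params: NeuronParams,
                               rng: np.random.Generator) -> np.ndarray:
    """Per-neuron fixed refractory durations (ms), sampled once."""
    d = rng.gamma(shape=params.refr_shape, scale=params.refr_scale, size=n)
    return np.maximum(d, DT_MS)
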