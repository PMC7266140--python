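"""Plasticity-parameter search and the robustness perturbation harness.

The cost of a candidate parameter set penalizes the mismatch between the
active sets of a CREATE and the subsequent RECALL, in the content space and
(down-weighted by ``lambda``) in the neural space:

    C = |A_C^CREATE sym-diff A_C^RECALL| + lambda * |A_S^CREATE sym-diff A_S^RECALL|

Optimization is gradient-free: a Latin-hypercube screen picks the best of
230 candidates, then stochastic hill climbing with linearly decaying
proposal widths refines it (accept only strictly lower cost).  The
robustness harness perturbs the 20 non-shape plasticity parameters
multiplicatively and re-runs the recall protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .params import (DEFAULT_TABLES, OPTIMIZED_PARAMS, ROBUSTNESS_PARAMS,
                     ConnectionTables, apply_overrides)

COST_LAMBDA = 1e-4


@dataclass(frozen=True)
class ParamSpec:
    """One tunable plasticity parameter with its allowed range."""

    table_key: str     # e.g. "S:E->E"
    field_name: str    # e.g. "tau_plus"
    lower: float
    upper: float

    def __post_init__(self):
        if not self.lower < self.upper:
            raise ValueError("lower bound must be below upper bound")

    @property
    def name(self) -> str:
        return f"{self.table_key}:{self.field_name}"

    @property
    def width(self) -> float:
        return self.upper - self.lower


@dataclass(frozen=True)
class CostValue:
    """Eq.-style mismatch cost with its components."""

    content_mismatch: int
    neural_mismatch: int
    lam: float = COST_LAMBDA

    @property
    def cost(self) -> float:
        return self.content_mismatch + self.lam * self.neural_mismatch


def cost(create_active_C, recall_active_C, create_active_S, recall_active_S,
         lam: float = COST_LAMBDA) -> CostValue:
    """Symmetric-difference cost between CREATE and RECALL active sets."""
    dC = len(np.setxor1d(np.asarray(create_active_C),
                         np.asarray(recall_active_C)))
    dS = len(np.setxor1d(np.asarray(create_active_S),
                         np.asarray(recall_active_S)))
    return CostValue(content_mismatch=dC, neural_mismatch=dS, lam=lam)


def default_search_space(tables: ConnectionTables = DEFAULT_TABLES
                         ) -> list[ParamSpec]:
    """Bounds for the 23 optimized parameters.

    The published table does not print the search bounds; the shipped
    defaults span [0.2x, 5x] of the canonical value for time constants and
    learning rates, [0, 2x] for amplitudes/weights, and [-1, 1] for the
    shape factor alpha.
    """
    specs = []
    for key, fieldname in OPTIMIZED_PARAMS:
        v = getattr(tables.plastic[key], fieldname)
        if fieldname in ("tau_plus", "tau_minus", "eta"):
            lo, hi = 0.2 * v, 5.0 * v
        elif fieldname == "alpha":
            lo, hi = -1.0, 1.0
        else:  # weights, bounds, offsets
            ref = v if v > 0 else 0.5
            lo, hi = 0.0, 2.0 * ref
        specs.append(ParamSpec(key, fieldname, lo, hi))
    return specs


def lhs_init(specs: Sequence[ParamSpec], evaluator: Callable[[np.ndarray], float],
             rng: np.random.Generator, n_candidates: int = 230
             ) -> tuple[np.ndarray, float, np.ndarray]:
    """Latin-hypercube screen; returns (best vector, best cost, all costs).

    One sample per stratum and dimension: candidate ``i`` takes a uniform
    draw from a random stratum of each parameter's range, with independent
    stratum permutations per dimension.
    """
    d = len(specs)
    u = np.empty((n_candidates, d))
    for j in range(d):
        strata = rng.permutation(n_candidates)
        u[:, j] = (strata + rng.random(n_candidates)) / n_candidates
    lo = np.array([s.lower for s in specs])
    width = np.array([s.width for s in specs])
    cand = lo + u * width
    costs = np.array([evaluator(cand[i]) for i in range(n_candidates)])
    if not np.all(np.isfinite(costs)):
        raise ValueError("evaluator returned a non-finite cost")
    best = int(np.argmin(costs))  # ties: first index
    return cand[best].copy(), float(costs[best]), costs


@dataclass
class HillClimbTrace:
    iterations: list[dict] = field(default_factory=list)

    def to_rows(self):
        return self.iterations


def hillclimb(start: np.ndarray, specs: Sequence[ParamSpec],
              evaluator: Callable[[np.ndarray], float],
              rng: np.random.Generator, n_iter: int = 500,
              p_modify: float = 0.5,
              validator: Callable[[np.ndarray], float] | None = None
              ) -> tuple[np.ndarray, float, HillClimbTrace]:
    """Greedy stochastic hill climbing with decaying proposal width.

    Each iteration modifies a Bernoulli(p_modify) subset of parameters by
    uniform proposals centered on the current value; the half-width decays
    linearly from half the allowed range to 0.1% of it.  A proposal is kept
    only if its cost is strictly lower.  If ``validator`` is given (cost on
    held-out instances), the visited parameter set minimizing it is
    returned (early stopping); otherwise the final accepted set.
    """
    x = np.asarray(start, float).copy()
    lo = np.array([s.lower for s in specs])
    hi = np.array([s.upper for s in specs])
    width = hi - lo
    c = float(evaluator(x))
    trace = HillClimbTrace()
    best_val, best_val_x = np.inf, x.copy()
    if validator is not None:
        best_val = float(validator(x))
    for it in range(n_iter):
        frac = 0.5 + (0.001 - 0.5) * (it / max(n_iter - 1, 1))
        mask = rng.random(len(x)) < p_modify
        prop = x.copy()
        delta = rng.uniform(-1.0, 1.0, size=len(x)) * frac * width
        prop[mask] = np.clip(x[mask] + delta[mask], lo[mask], hi[mask])
        c_prop = float(evaluator(prop))
        accepted = c_prop < c
        if accepted:
            x, c = prop, c_prop
            if validator is not None:
                v = float(validator(x))
                if v < best_val:
                    best_val, best_val_x = v, x.copy()
        trace.iterations.append(
            {"iter": it, "accepted": accepted, "cost": c_prop,
             "width_frac": frac})
    if validator is not None:
        return best_val_x, best_val, trace
    return x, c, trace


@dataclass(frozen=True)
class RobustnessConfig:
    """Multiplicative-noise perturbation of the plasticity parameters."""

    sigma_param: float
    n_samples: int = 100
    params: tuple[tuple[str, str], ...] = ROBUSTNESS_PARAMS

    def __post_init__(self):
        if self.sigma_param < 0:
            raise ValueError("sigma_param must be non-negative")


def perturb(tables: ConnectionTables, sigma_param: float,
            rng: np.random.Generator,
            which: Sequence[tuple[str, str]] = ROBUSTNESS_PARAMS
            ) -> ConnectionTables:
    """Sample each selected parameter from Normal(v, (sigma*v)^2), clipped.

    Clipping rules: time constants are forced non-negative (floored just
    above zero so the exponentials stay defined), and initial-weight
    intervals are reordered so the upper bound of the uniform distribution
    is not below the lower one.
    """
    overrides: dict[tuple[str, str], float] = {}
    for key, fieldname in which:
        v = getattr(tables.plastic[key], fieldname)
        nv = rng.normal(v, abs(sigma_param * v)) if sigma_param > 0 else v
        if fieldname in ("tau_plus", "tau_minus"):
            nv = max(nv, 1e-6)
        elif fieldname == "w_max":
            nv = max(nv, 0.0)  # clipping bound may not drop below w_min = 0
        overrides[(key, fieldname)] = nv
    # re-order init bounds if sampling inverted them
    for key in {k for k, _ in which}:
        lo_key, hi_key = (key, "w_init_lo"), (key, "w_init_hi")
        lo = overrides.get(lo_key, tables.plastic[key].w_init_lo)
        hi = overrides.get(hi_key, tables.plastic[key].w_init_hi)
        if hi < lo:
            overrides[lo_key], overrides[hi_key] = hi, lo
    return apply_overrides(tables, overrides)
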