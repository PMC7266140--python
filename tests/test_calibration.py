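"""Cost function, Latin-hypercube screen, hill climbing, perturbations."""

import numpy as np
import pytest

from apsim.calibration import (ParamSpec, cost, default_search_space,
                               hillclimb, lhs_init, perturb)
from apsim.params import DEFAULT_TABLES, ROBUSTNESS_PARAMS


class TestCost:
    def test_identical_sets_zero(self):
        assert cost([1, 2, 3], [1, 2, 3], [4, 5], [4, 5]).cost == 0.0

    def test_component_weighting(self):
        c = cost([1, 2, 3, 4], [5, 6, 7, 8], list(range(10)), [])
        assert c.content_mismatch == 8   # disjoint 4-sets
        assert c.neural_mismatch == 10
        assert c.cost == pytest.approx(8.001)

    def test_example_value(self):
        c = cost([1, 2, 3, 4], [3, 4, 5, 6], list(range(10)),
                 list(range(5, 15)))
        assert c.content_mismatch == 4
        assert c.neural_mismatch == 10
        assert c.cost == pytest.approx(4.001)

    def test_symmetric_in_create_recall(self):
        a = cost([1, 2], [2, 3], [1], [9])
        b = cost([2, 3], [1, 2], [9], [1])
        assert a.cost == b.cost


class TestLHS:
    def test_one_sample_per_stratum(self):
        spec = [ParamSpec("C:E->E", "eta", 0.0, 1.0)]
        seen = []
        lhs_init(spec, lambda x: seen.append(x[0]) or 0.0,
                 np.random.default_rng(0), n_candidates=10)
        strata = sorted(int(10 * v) for v in seen)
        assert strata == list(range(10))

    def test_constant_evaluator_returns_first(self):
        spec = [ParamSpec("C:E->E", "eta", 0.0, 1.0)]
        x, c, costs = lhs_init(spec, lambda x: 1.0,
                               np.random.default_rng(1), n_candidates=5)
        assert c == 1.0

    def test_quadratic_toy_lands_near_optimum(self):
        spec = [ParamSpec("C:E->E", "eta", 0.0, 1.0),
                ParamSpec("C:E->E", "tau_plus", 0.0, 1.0)]
        hits = 0
        for seed in range(10):
            x, c, _ = lhs_init(
                spec, lambda v: float(np.sum((v - 0.4) ** 2)),
                np.random.default_rng(seed), n_candidates=100)
            hits += np.all(np.abs(x - 0.4) < 0.15)
        assert hits >= 9


class TestHillclimb:
    SPEC = [ParamSpec("C:E->E", "eta", 0.0, 1.0),
            ParamSpec("C:E->E", "tau_plus", 0.0, 1.0)]

    def test_at_optimum_stays(self):
        x0 = np.array([0.5, 0.5])
        x, c, _ = hillclimb(x0, self.SPEC,
                            lambda v: float(np.sum((v - 0.5) ** 2)),
                            np.random.default_rng(0), n_iter=50)
        assert c == 0.0 and np.array_equal(x, x0)

    def test_accepted_costs_strictly_decrease(self):
        def f(v):
            return float(np.sum((v - 0.3) ** 2))

        x, c, trace = hillclimb(np.array([0.9, 0.9]), self.SPEC, f,
                                np.random.default_rng(1), n_iter=200)
        accepted = [r["cost"] for r in trace.iterations if r["accepted"]]
        assert all(b < a for a, b in zip(accepted, accepted[1:]))
        assert c <= f(np.array([0.9, 0.9]))

    def test_toy_minimum_recovered_for_most_seeds(self):
        def f(v):
            return float(np.sum((v - 0.3) ** 2))

        good = 0
        for seed in range(10):
            x, c, _ = hillclimb(np.array([0.9, 0.9]), self.SPEC, f,
                                np.random.default_rng(seed), n_iter=500)
            good += np.all(np.abs(x - 0.3) < 0.01)
        assert good >= 9

    def test_early_stopping_uses_validator(self):
        def f(v):
            return float(np.sum((v - 0.3) ** 2))

        def val(v):
            return float(np.sum((v - 0.7) ** 2))

        x, v, _ = hillclimb(np.array([0.9, 0.9]), self.SPEC, f,
                            np.random.default_rng(2), n_iter=300,
                            validator=val)
        # returned vector minimizes the validation cost among visited ones
        assert val(x) == pytest.approx(v)
        assert v <= val(np.array([0.9, 0.9]))


class TestPerturb:
    def test_sigma_zero_identity(self):
        t = perturb(DEFAULT_TABLES, 0.0, np.random.default_rng(0))
        for key, row in DEFAULT_TABLES.plastic.items():
            assert t.plastic[key] == row

    def test_twenty_parameters_in_default_subset(self):
        assert len(ROBUSTNESS_PARAMS) == 20
        assert all(f != "alpha" for _, f in ROBUSTNESS_PARAMS)

    def test_time_constants_stay_positive(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            t = perturb(DEFAULT_TABLES, 2.0, rng)
            for row in t.plastic.values():
                assert row.tau_plus > 0
                assert row.tau_minus is None or row.tau_minus > 0

    def test_init_interval_stays_ordered(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            t = perturb(DEFAULT_TABLES, 1.0, rng)
            for row in t.plastic.values():
                assert row.w_init_hi >= row.w_init_lo

    def test_empirical_sd_matches_requested(self):
        rng = np.random.default_rng(3)
        v0 = DEFAULT_TABLES.plastic["S:E->E"].eta
        draws = [perturb(DEFAULT_TABLES, 0.2, rng).plastic["S:E->E"].eta
                 for _ in range(2000)]
        assert np.std(draws) == pytest.approx(0.2 * v0, rel=0.1)


def test_default_search_space_covers_all_tunables():
    specs = default_search_space()
    assert len(specs) == 23
    names = {s.name for s in specs}
    assert "S:E->E:tau_minus" in names and "C:E->E:tau_minus" in names
    for s in specs:
        assert s.lower < s.upper
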