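"""Pairing rule, trace-vs-brute-force equivalence, gating, depression."""

import numpy as np
import pytest

import apsim
from apsim.params import DEFAULT_TABLES, STDPParams, TMParams
from apsim.plasticity import (apply_pairings, pairing_updates_bruteforce,
                              stdp_delta, tm_efficacy, tm_steady_state)

CEE = DEFAULT_TABLES.plastic["C:E->E"]   # eta 0.0025, A- 0.5, tau+ 25
XE = DEFAULT_TABLES.plastic["C:X->E"]    # alpha 0 (no anti-causal branch)


class TestStdpDelta:
    def test_coincident_pairing(self):
        assert stdp_delta(0.0, CEE) == pytest.approx(
            CEE.eta * (1 - CEE.A_minus))  # +0.00125

    def test_one_tau_causal(self):
        assert stdp_delta(25.0, CEE) == pytest.approx(
            0.0025 * (np.exp(-1.0) - 0.5), rel=1e-12)  # ~ -0.000330

    def test_pure_offset_at_large_lag(self):
        assert stdp_delta(1e7, CEE) == pytest.approx(-CEE.eta * CEE.A_minus)

    def test_no_anticausal_branch_when_alpha_zero(self):
        assert stdp_delta(-5.0, XE) == 0.0

    def test_non_finite_raises(self):
        with pytest.raises(ValueError):
            stdp_delta(np.nan, CEE)


def _random_instance(seed, n_spk=20, alpha=-1.0):
    rng = np.random.default_rng(seed)
    params = STDPParams(eta=0.01, alpha=alpha, tau_plus=20.0,
                        tau_minus=None if alpha == 0 else 35.0,
                        A_minus=0.4, w_min=0.0, w_max=10.0,
                        w_init_lo=5.0, w_init_hi=5.0,
                        delay_lo=1.0, delay_hi=1.0)
    pre_t = np.sort(rng.uniform(0, 500, size=n_spk))
    post_t = np.sort(rng.uniform(0, 500, size=n_spk))
    return params, pre_t, post_t


class TestApplyPairings:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    @pytest.mark.parametrize("alpha", [0.0, -1.0, 0.5])
    def test_matches_bruteforce_all_pairs(self, seed, alpha):
        """Incremental traces equal the quadratic sum (no clipping active)."""
        params, pre_t, post_t = _random_instance(seed, alpha=alpha)
        edges = (np.array([0]), np.array([0]))
        w = np.array([5.0])
        apply_pairings((np.zeros(len(pre_t), int), pre_t),
                       (np.zeros(len(post_t), int), post_t),
                       edges, w, params)
        expected = 5.0 + pairing_updates_bruteforce(pre_t, post_t, params)
        assert w[0] == pytest.approx(expected, rel=1e-9)

    def test_three_edge_group(self):
        params, _, _ = _random_instance(7)
        rng = np.random.default_rng(7)
        pre = (rng.integers(0, 2, 30), np.sort(rng.uniform(0, 300, 30)))
        post = (rng.integers(0, 2, 30), np.sort(rng.uniform(0, 300, 30)))
        edges = (np.array([0, 0, 1]), np.array([0, 1, 1]))
        w = np.full(3, 5.0)
        apply_pairings(pre, post, edges, w, params)
        for k in range(3):
            pre_t = pre[1][pre[0] == edges[0][k]]
            post_t = post[1][post[0] == edges[1][k]]
            expected = 5.0 + pairing_updates_bruteforce(pre_t, post_t, params)
            assert w[k] == pytest.approx(expected, rel=1e-9)

    def test_no_spikes_no_change(self):
        params, _, _ = _random_instance(0)
        w = np.array([5.0])
        apply_pairings((np.array([], int), np.array([])),
                       (np.array([], int), np.array([])),
                       (np.array([0]), np.array([0])), w, params)
        assert w[0] == 5.0

    def test_single_coincident_pair(self):
        # causal-branch-only group: the single dt = 0 pairing is the whole
        # update
        params, _, _ = _random_instance(0, alpha=0.0)
        w = np.array([5.0])
        apply_pairings((np.array([0]), np.array([10.0])),
                       (np.array([0]), np.array([10.0])),
                       (np.array([0]), np.array([0])), w, params)
        assert w[0] == pytest.approx(5.0 + stdp_delta(0.0, params))

    def test_closed_gate_changes_nothing(self):
        params, pre_t, post_t = _random_instance(1)
        w = np.array([5.0])
        apply_pairings((np.zeros(len(pre_t), int), pre_t),
                       (np.zeros(len(post_t), int), post_t),
                       (np.array([0]), np.array([0])), w, params,
                       gate_open=False)
        assert w[0] == 5.0

    def test_spike_outside_window_rejected(self):
        params, pre_t, post_t = _random_instance(1)
        with pytest.raises(ValueError):
            apply_pairings((np.zeros(len(pre_t), int), pre_t),
                           (np.zeros(len(post_t), int), post_t),
                           (np.array([0]), np.array([0])), np.array([5.0]),
                           params, t_window=(0.0, 100.0))

    def test_weights_always_inside_bounds(self):
        params, pre_t, post_t = _random_instance(5, n_spk=50)
        # tight bounds force clipping on the way
        params = STDPParams(eta=0.5, alpha=-1.0, tau_plus=20.0,
                            tau_minus=35.0, A_minus=0.4, w_min=0.0,
                            w_max=1.0, w_init_lo=0.5, w_init_hi=0.5,
                            delay_lo=1.0, delay_hi=1.0)
        w = np.array([0.5])
        apply_pairings((np.zeros(len(pre_t), int), pre_t),
                       (np.zeros(len(post_t), int), post_t),
                       (np.array([0]), np.array([0])), w, params)
        assert 0.0 <= w[0] <= 1.0


class TestEngineStdpOracle:
    def test_engine_updates_equal_offline_replay(self, tiny_engine_factory):
        """The compiled kernel's bookkeeping equals the offline pairing rule.

        Run a small network with plastic input synapses, then replay the
        recorded spike trains through :func:`apply_pairings` starting from
        the initial weights; the engine's final weights must match.
        """
        eng = tiny_engine_factory(seed=5)
        eng.set_lock("C", False)
        gname = "X->C"
        gi = eng.net.group_index[gname]
        eids = eng.net.group_eids[gi]
        w0 = eng.net.e_w[eids].copy()
        pre0, post0 = eng.net.e_pre[eids].copy(), eng.net.e_post[eids].copy()
        eng.advance(400.0, np.full(40, 30.0))
        rec = eng.record()
        xi, xt = rec.for_population("X")
        ci, ct = rec.for_population("C.E")
        grp = eng.net.groups[gi]
        params = grp.params
        w = w0.copy()
        apply_pairings((xi, xt), (ci, ct),
                       (pre0 - eng.net.n_real, post0), w, params)
        np.testing.assert_allclose(eng.net.e_w[eids], w, rtol=1e-9)

    def test_frozen_group_is_bit_identical(self, tiny_engine_factory):
        eng = tiny_engine_factory(seed=6)
        eng.set_lock("C", False)
        eng.freeze_group("X->C")
        eng.freeze_group("C.E->E")
        w0 = eng.net.e_w.copy()
        eng.advance(400.0, np.full(40, 30.0))
        assert np.array_equal(eng.net.e_w, w0)


class TestShortTermDepression:
    def test_first_spike_full_resources(self):
        tm = TMParams()
        assert tm_efficacy([0.0], tm)[0] == pytest.approx(tm.U)

    def test_full_recovery_at_long_gaps(self):
        eff = tm_efficacy([0.0, 1e6], TMParams())
        assert eff[1] == pytest.approx(eff[0], rel=1e-9)

    def test_depression_approaches_steady_state(self):
        tm = TMParams()
        t = np.arange(300) * 10.0  # 100 Hz
        eff = tm_efficacy(t, tm)
        # after the small initial facilitation bump, efficacy falls
        # monotonically towards the fixed point
        assert np.all(np.diff(eff[1:10]) < 0)
        assert eff[-1] == pytest.approx(tm_steady_state(100.0, tm), rel=1e-6)

    def test_non_monotone_times_rejected(self):
        with pytest.raises(ValueError):
            tm_efficacy([0.0, 5.0, 3.0], TMParams())
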