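"""Wiring statistics, parameter placement, component independence."""

import numpy as np
import pytest

import apsim
from apsim.network import NetworkModel, bernoulli_pairs, component_rng
from apsim.params import DEFAULT_TABLES


@pytest.fixture(scope="module")
def model():
    m = NetworkModel(master_seed=5)
    m.add_content_space()
    m.add_neural_space("S1")
    return m


@pytest.fixture(scope="module")
def net(model):
    return model.compile()


class TestSizes:
    def test_four_to_one_ratio(self, model):
        assert model.content.n_inh == 250
        assert model.space("S1").n_inh == 500

    def test_invalid_size_rejected(self):
        m = NetworkModel(1)
        with pytest.raises(ValueError):
            m.add_content_space(n_exc=1001)


def _group(model, name):
    return next(g for g in model.groups if g.name == name)


class TestWiring:
    @pytest.mark.parametrize("name,n_pre,n_post,p,self_excluded", [
        ("C.E->E", 1000, 1000, 0.1, True),
        ("C.E->I", 1000, 250, 0.575, False),
        ("C.I->E", 250, 1000, 0.6, False),
        ("C.I->I", 250, 250, 0.55, True),
        ("C->S1", 1000, 2000, 0.1, False),
        ("S1->C", 2000, 1000, 0.1, False),
        ("S1.E->E", 2000, 2000, 0.1, True),
    ])
    def test_edge_counts_within_binomial_bounds(self, model, name, n_pre,
                                                n_post, p, self_excluded):
        g = _group(model, name)
        n_pairs = n_pre * n_post - (n_pre if self_excluded else 0)
        mean = n_pairs * p
        sd = np.sqrt(n_pairs * p * (1 - p))
        assert abs(len(g) - mean) < 4 * sd

    def test_input_is_all_to_all(self, model):
        assert len(_group(model, "X->C")) == 200 * 1000

    def test_no_self_connections(self, model):
        for name in ("C.E->E", "S1.E->E", "C.I->I"):
            g = _group(model, name)
            assert not np.any(g.pre == g.post)

    def test_plastic_delays_within_tabulated_bounds(self, model):
        g = _group(model, "C->S1")
        assert g.delay_ms.min() >= 1.0 and g.delay_ms.max() <= 10.0
        g = _group(model, "C.E->E")
        assert np.all(g.delay_ms == 1.0)

    def test_initial_weights_within_bounds(self, model):
        for name, key in (("C->S1", "S:C->E"), ("S1->C", "C:S->E")):
            g = _group(model, name)
            row = DEFAULT_TABLES.plastic[key]
            assert g.w.min() >= row.w_init_lo - 1e-12
            assert g.w.max() <= row.w_init_hi + 1e-12

    def test_zero_probability_gives_no_edges(self):
        pre, post = bernoulli_pairs(50, 50, 0.0, np.random.default_rng(0))
        assert len(pre) == 0


class TestNeuronPlacement:
    def test_bias_current_only_for_excitatory(self, model, net):
        c = model.content
        assert np.all(net.bias_term[c.exc_slice] > 0)
        assert np.all(net.bias_term[c.inh_slice] == 0)

    def test_excitability_only_in_neural_space_exc(self, model, net):
        c, s = model.content, model.space("S1")
        assert np.all(net.q_sfa[c.exc_slice] == 0)
        assert np.all(net.q_sfa[s.exc_slice] == 0.02)
        assert np.all(net.q_sfa[s.inh_slice] == 0)

    def test_static_weights_carry_spacewise_scale(self, model):
        gC = _group(model, "C.E->I")
        gS = _group(model, "S1.E->I")
        assert gC.w[0] == pytest.approx(17.39 * model.static_scale["content"])
        assert gS.w[0] == pytest.approx(17.39 * model.static_scale["neural"])


class TestComponentIndependence:
    def test_adding_a_space_never_perturbs_existing_wiring(self):
        m1 = NetworkModel(master_seed=9)
        m1.add_content_space()
        m1.add_neural_space("S1")
        snapshot = {g.name: (g.pre.copy(), g.post.copy(), g.w.copy())
                    for g in m1.groups}
        m1.add_neural_space("S2")
        for name, (pre, post, w) in snapshot.items():
            g = next(g for g in m1.groups if g.name == name)
            assert np.array_equal(g.pre, pre)
            assert np.array_equal(g.post, post)
            assert np.array_equal(g.w, w)

    def test_component_streams_are_reproducible(self):
        a = component_rng(4, "space:C").random(3)
        b = component_rng(4, "space:C").random(3)
        assert np.array_equal(a, b)


class TestWeightPersistence:
    def test_pull_weights_round_trips_through_recompile(self):
        m = NetworkModel(master_seed=2, n_in=40)
        m.add_content_space(n_exc=200)
        net = m.compile()
        eng = apsim.Engine(net, seed=1)
        eng.set_lock("C", False)
        eng.advance(300.0, np.full(40, 30.0))
        trained = {g.name: net.group_weights(g.name).copy()
                   for g in net.groups}
        net.pull_weights()
        net2 = m.compile()
        for name, w in trained.items():
            assert np.array_equal(net2.group_weights(name), w)
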