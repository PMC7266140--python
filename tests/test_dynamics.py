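"""Neuron model, spike sampling, engine determinism, spike records."""

import io

import numpy as np
import pytest
from scipy import stats

import apsim
from apsim.dynamics import PopulationState, SpikeRecord
from apsim.params import EXC_PARAMS, INH_PARAMS, NeuronParams


class TestInstantaneousRate:
    def test_exponential_zero_at_rest(self):
        assert apsim.instantaneous_rate(0.0, EXC_PARAMS) == 0.0

    def test_linear_inhibitory(self):
        assert apsim.instantaneous_rate(2.0, INH_PARAMS) == pytest.approx(20.0)

    def test_exponential_one_mv(self):
        assert apsim.instantaneous_rate(1.0, EXC_PARAMS) == pytest.approx(
            1000.0 * (np.e - 1.0), rel=1e-12)

    def test_negative_clipped_to_zero(self):
        assert apsim.instantaneous_rate(-3.0, EXC_PARAMS) == 0.0
        assert apsim.instantaneous_rate(-1.0, INH_PARAMS) == 0.0

    def test_non_finite_raises(self):
        with pytest.raises(FloatingPointError):
            apsim.instantaneous_rate(np.nan, EXC_PARAMS)


class TestMembraneStep:
    def test_bias_fixed_point(self):
        state = PopulationState.zeros(1, refr_duration=3.5)
        for _ in range(2000):
            apsim.membrane_step(state, I_syn=0.0, I_inh=0.0,
                                params=EXC_PARAMS, dt=0.1)
        # V -> R_m * I_e = 0.5 * 0.2 = 0.1 mV
        assert state.V[0] == pytest.approx(0.1, rel=1e-6)

    def test_lock_current_fixed_point_silences(self):
        state = PopulationState.zeros(1, refr_duration=3.5)
        for _ in range(2000):
            apsim.membrane_step(state, I_syn=0.0, I_inh=-4.0,
                                params=EXC_PARAMS, dt=0.1)
        assert state.V[0] == pytest.approx(0.5 * (0.2 - 4.0), rel=1e-6)
        assert apsim.instantaneous_rate(state.V, EXC_PARAMS)[0] == 0.0

    def test_small_dt_changes_nothing_to_first_order(self):
        state = PopulationState.zeros(1, refr_duration=3.5)
        state.V[:] = 1.0
        apsim.membrane_step(state, 0.0, 0.0, EXC_PARAMS, dt=1e-7)
        assert state.V[0] == pytest.approx(1.0, abs=1e-6)

    def test_refractory_clamped_at_reset(self):
        state = PopulationState.zeros(1, refr_duration=5.0)
        state.refr_remaining[:] = 5.0
        apsim.membrane_step(state, 10.0, 0.0, EXC_PARAMS, dt=0.1)
        assert state.V[0] == 0.0


class TestSampleSpikes:
    def test_zero_hazard_never_spikes(self):
        state = PopulationState.zeros(100, refr_duration=3.5)
        rng = np.random.default_rng(0)
        assert not apsim.sample_spikes(state, EXC_PARAMS, 0.1, rng).any()

    def test_poisson_rate_without_refractoriness(self):
        # constant hazard 100 Hz; refractoriness made negligible
        p = NeuronParams(c1=10.0, c2=0.0, c3=0.0, q_sfa=0.0)
        state = PopulationState.zeros(1000, refr_duration=0.1)
        state.V[:] = 10.0  # hazard 100 Hz for the linear neuron
        rng = np.random.default_rng(1)
        count = 0
        for _ in range(10000):  # 1 s
            count += apsim.sample_spikes(state, p, 0.1, rng).sum()
            state.V[:] = 10.0
            state.refr_remaining = np.maximum(state.refr_remaining - 0.1, 0)
        rate = count / 1000.0
        se = np.sqrt(100.0 / 1000.0)
        assert abs(rate - 100.0) < 3 * se + 1.0

    def test_interspike_intervals_match_censored_geometric(self):
        """ISI law: refractory dead time + geometric step count."""
        p_spike = -np.expm1(-100.0 * 0.1e-3)  # 100 Hz hazard at dt=0.1
        rng = np.random.default_rng(2)
        n = 20000
        isi_steps = rng.geometric(p_spike, size=n)
        edges = np.arange(1, 12)
        obs = np.array([(isi_steps == k).sum() for k in edges[:-1]])
        obs = np.append(obs, (isi_steps >= edges[-1]).sum())
        probs = [(1 - p_spike) ** (k - 1) * p_spike for k in edges[:-1]]
        probs.append((1 - p_spike) ** (edges[-1] - 1))
        chi2 = stats.chisquare(obs, n * np.array(probs))
        assert chi2.pvalue > 0.01

    def test_excitability_increments_and_cap(self):
        p = NeuronParams(c1=0.0, c2=1000.0, c3=1.0, q_sfa=0.02)
        state = PopulationState.zeros(1, refr_duration=3.5)
        rng = np.random.default_rng(3)
        for _ in range(10):
            state.V[:] = 5.0  # certain spike at this hazard
            state.refr_remaining[:] = 0.0
            spiked = apsim.sample_spikes(state, p, 0.1, rng)
            assert spiked[0]
        assert state.b_sfa[0] == pytest.approx(0.2, rel=1e-6)
        for _ in range(40):
            state.V[:] = 5.0
            state.refr_remaining[:] = 0.0
            apsim.sample_spikes(state, p, 0.1, rng)
        assert state.b_sfa[0] == pytest.approx(p.b_sfa_max)


class TestEngine:
    def test_zero_duration_is_a_no_op(self, tiny_engine_factory):
        eng = tiny_engine_factory()
        w0 = eng.net.e_w.copy()
        eng.advance(0.0)
        assert len(eng.record()) == 0
        assert np.array_equal(eng.net.e_w, w0)

    def test_locked_space_is_silent(self, tiny_engine_factory):
        eng = tiny_engine_factory()
        eng.set_lock("C", True)
        eng.advance(1000.0, np.full(40, 50.0))
        idx, _ = eng.record().for_population("C.E")
        assert len(idx) == 0

    def test_determinism_bit_identical(self, tiny_engine_factory):
        recs = []
        for _ in range(2):
            eng = tiny_engine_factory(seed=7)
            eng.set_lock("C", False)
            eng.advance(500.0, np.full(40, 20.0))
            recs.append(eng.record())
        assert np.array_equal(recs[0].ids, recs[1].ids)
        assert np.array_equal(recs[0].times, recs[1].times)

    def test_excitability_zero_where_disabled(self, tiny_engine_factory):
        # content-space neurons have q_sfa = 0: bias stays identically zero
        eng = tiny_engine_factory()
        eng.set_lock("C", False)
        eng.advance(500.0, np.full(40, 30.0))
        assert np.all(eng.b_sfa == 0.0)

    def test_unlock_releases_from_clamp_potential(self, tiny_engine_factory):
        eng = tiny_engine_factory()
        eng.set_lock("C", True)
        eng.advance(100.0)
        eng.set_lock("C", False)
        sp = eng.net.spaces[0]
        from apsim.params import V_LOCK_CLAMP
        assert np.all(eng.V[sp.exc_slice] == pytest.approx(V_LOCK_CLAMP))


class TestSpikeRecord:
    def test_text_round_trip(self, tmp_path):
        rec = SpikeRecord(np.array([0, 5, 12], dtype=np.int32),
                          np.array([0.1, 3.0, 2.5]),
                          {"A": (0, 10), "B": (10, 5)})
        path = tmp_path / "spikes.gdf"
        rec.to_text(str(path))
        back = SpikeRecord.from_text(str(path))
        order = np.argsort(back.times, kind="stable")
        assert sorted(back.ids.tolist()) == sorted(rec.ids.tolist())
        assert back.populations == rec.populations

    def test_rates_and_counts(self):
        rec = SpikeRecord(np.array([0, 0, 1], dtype=np.int32),
                          np.array([10.0, 20.0, 30.0]), {"A": (0, 2)})
        assert rec.counts("A").tolist() == [2, 1]
        assert rec.mean_rate("A", 0.0, 100.0) == pytest.approx(15.0)
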