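"""Trace filtering, assembly rules, similarity, decoding, voxelization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from apsim.analysis import (SimilarityReport, VoxelPartition,
                            identify_assembly, lowpass, similarity,
                            train_decoder, voxelize)
from apsim.dynamics import SpikeRecord


def _record(ids, times, n=5, name="P"):
    return SpikeRecord(np.asarray(ids, dtype=np.int32),
                       np.asarray(times, float), {name: (0, n)})


class TestLowpass:
    def test_single_spike_kernel_value(self):
        rec = _record([0], [100.0])
        r = lowpass(rec, "P", [120.0])
        assert r[0, 0] == pytest.approx(np.exp(-1.0))

    def test_truncation_beyond_window(self):
        rec = _record([0], [100.0])
        r = lowpass(rec, "P", [201.0])
        assert r[0, 0] == 0.0

    def test_matches_bruteforce_convolution(self):
        rng = np.random.default_rng(0)
        times = np.sort(rng.uniform(0, 400, 200))
        ids = rng.integers(0, 5, 200)
        rec = _record(ids, times)
        grid = np.arange(50.0, 400.0, 7.0)
        r = lowpass(rec, "P", grid)
        for gi, t in enumerate(grid):
            for n in range(5):
                expected = sum(np.exp(-(t - ts) / 20.0)
                               for ts in times[ids == n]
                               if t - 100.0 <= ts <= t)
                assert r[gi, n] == pytest.approx(expected, rel=1e-9, abs=1e-12)


class TestIdentifyAssembly:
    def test_silent_population_empty(self):
        rec = _record([], [])
        assert len(identify_assembly(rec, "P", 0.0, 100.0)) == 0

    def test_threshold_is_strict(self):
        # 6 spikes in 100 ms = 60 Hz -> in; 5 spikes = 50 Hz -> out
        rec = _record([0] * 6 + [1] * 5, list(np.linspace(1, 99, 6))
                      + list(np.linspace(1, 99, 5)))
        asm = identify_assembly(rec, "P", 0.0, 100.0)
        assert asm.tolist() == [0]

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            identify_assembly(_record([], []), "P", 10.0, 10.0)


class TestSimilarity:
    def test_pass_case(self):
        ref = np.arange(60)
        rec = np.concatenate([np.arange(50), np.arange(100, 105)])
        rep = similarity(ref, rec)
        assert rep.retained_fraction == pytest.approx(50 / 60)
        assert rep.excess_count == 5
        assert rep.passes

    def test_fail_below_retention(self):
        rep = similarity(np.arange(60), np.arange(47))
        assert not rep.passes

    def test_identity_passes(self):
        rep = similarity(np.arange(60), np.arange(60))
        assert rep.retained_fraction == 1.0 and rep.excess_count == 0
        assert rep.passes

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            similarity(np.array([]), np.arange(3))

    @given(st.sets(st.integers(0, 99), min_size=10, max_size=60),
           st.sets(st.integers(0, 99), max_size=60))
    @settings(max_examples=50, deadline=None)
    def test_adding_a_correct_neuron_never_flips_pass_to_fail(self, ref, rec):
        ref, rec = np.array(sorted(ref)), np.array(sorted(rec))
        before = similarity(ref, rec)
        missing = np.setdiff1d(ref, rec)
        if before.passes and len(missing):
            after = similarity(ref, np.append(rec, missing[0]))
            assert after.passes


class TestDecoder:
    def _toy(self, sep=5.0, n=40, seed=0):
        rng = np.random.default_rng(seed)
        traces, labels = [], []
        for k in range(3):
            mean = np.zeros(6)
            mean[2 * k:2 * k + 2] = sep
            traces.append(rng.normal(mean, 1.0, size=(n, 6)))
            labels.append(k)
        return traces, labels

    def test_separable_classes_zero_error(self):
        traces, labels = self._toy()
        dec = train_decoder(traces, labels)
        for tr, l in zip(traces, labels):
            assert dec.error(tr, l) == 0.0

    def test_permuted_labels_near_chance(self):
        traces, labels = self._toy(sep=5.0)
        dec = train_decoder(traces, [1, 2, 0])  # deliberately wrong labels
        errs = [dec.error(tr, l) for tr, l in zip(traces, labels)]
        assert np.mean(errs) > 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_decoder([np.zeros((5, 3))], [0])


class TestVoxelize:
    def test_equal_partition(self):
        part = VoxelPartition.draw(2000, 5, np.random.default_rng(0))
        assert all(len(g) == 400 for g in part.groups)
        used = np.concatenate(part.groups)
        assert len(np.unique(used)) == 2000

    def test_zero_activity_zero_noise(self):
        part = VoxelPartition.draw(100, 5, np.random.default_rng(0))
        sig = voxelize(np.zeros((10, 100)), part,
                       np.random.default_rng(1), noise_var=0.0)
        assert np.all(sig == 0.0)

    def test_linearity_without_noise(self):
        part = VoxelPartition.draw(100, 5, np.random.default_rng(0))
        rng = np.random.default_rng(2)
        tr = rng.random((10, 100))
        a = voxelize(tr, part, np.random.default_rng(3), noise_var=0.0)
        b = voxelize(2 * tr, part, np.random.default_rng(3), noise_var=0.0)
        np.testing.assert_allclose(b, 2 * a)
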