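"""Spike-train analysis: filtering, assemblies, similarity, decoding, voxels.

The low-pass trace of a spike train is the truncated exponential filter
``r_i(t) = sum_{t - T_LP <= t_s <= t} exp(-(t - t_s)/tau_LP)`` sampled on a
1 ms grid (``tau_LP = 20 ms``, ``T_LP = 100 ms``).  Assemblies are sets of
neurons exceeding a 50 Hz rate threshold in a measurement window; a recall
is similar to its reference assembly if at least 80% of the reference is
active and the excess count stays below 20% of the reference size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression

from .dynamics import SpikeRecord

TAU_LP = 20.0
T_LP = 100.0
RATE_THRESHOLD = 50.0


def lowpass(rec: SpikeRecord, population: str, t_grid,
            tau: float = TAU_LP, T: float = T_LP) -> np.ndarray:
    """Filtered activity matrix, shape ``(len(t_grid), n_neurons)``.

    Exact truncated-exponential sum over spikes; spikes older than ``T``
    contribute nothing.
    """
    t_grid = np.asarray(t_grid, float)
    idx, times = rec.for_population(population)
    n = rec.populations[population][1]
    order = np.argsort(times)
    idx, times = idx[order], times[order]
    r = np.zeros((len(t_grid), n))
    for k, t in enumerate(t_grid):
        lo = np.searchsorted(times, t - T)
        hi = np.searchsorted(times, t, side="right")
        np.add.at(r[k], idx[lo:hi], np.exp(-(t - times[lo:hi]) / tau))
    return r


def identify_assembly(rec: SpikeRecord, population: str, t0: float, t1: float,
                      threshold_hz: float = RATE_THRESHOLD) -> np.ndarray:
    """Neurons of ``population`` firing strictly above ``threshold_hz``."""
    if t1 <= t0:
        raise ValueError("window must have positive length")
    counts = rec.counts(population, t0, t1)
    rates = counts / ((t1 - t0) * 1e-3)
    return np.nonzero(rates > threshold_hz)[0]


@dataclass(frozen=True)
class SimilarityReport:
    """Retained-fraction / excess-count verdict of a recall."""

    original_size: int
    retained_fraction: float
    excess_count: int

    @property
    def passes(self) -> bool:
        return (self.retained_fraction >= 0.8
                and self.excess_count <= 0.2 * self.original_size)


def similarity(reference, recalled) -> SimilarityReport:
    """Compare a recalled active set against its reference assembly."""
    reference = np.asarray(reference)
    recalled = np.asarray(recalled)
    if len(reference) == 0:
        raise ValueError("reference assembly is empty")
    inter = len(np.intersect1d(reference, recalled))
    return SimilarityReport(
        original_size=len(reference),
        retained_fraction=inter / len(reference),
        excess_count=len(np.setdiff1d(recalled, reference)))


@dataclass
class LinearDecoder:
    """Multinomial logistic-regression readout over trace features."""

    model: LogisticRegression
    classes: np.ndarray
    feature_subset: np.ndarray | None = None

    def _features(self, traces: np.ndarray) -> np.ndarray:
        if self.feature_subset is not None:
            return traces[:, self.feature_subset]
        return traces

    def classify(self, traces: np.ndarray) -> np.ndarray:
        """Predict one class per 1 ms sample."""
        return self.model.predict(self._features(traces))

    def error(self, traces: np.ndarray, label) -> float:
        """Fraction of misclassified samples."""
        return float(np.mean(self.classify(traces) != label))


def train_decoder(trace_list, labels, feature_subset=None,
                  C: float = 1.0, max_iter: int = 2000) -> LinearDecoder:
    """Fit a linear readout on labeled trace matrices.

    ``trace_list`` holds one ``(n_samples, n_neurons)`` matrix per trial;
    ``labels`` one label per trial.  Ridge-regularized multinomial logistic
    regression at fixed strength (the library default ``C = 1``).
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least two classes to train a decoder")
    X = np.vstack(trace_list)
    y = np.concatenate([np.full(len(t), l) for t, l in zip(trace_list, labels)])
    subset = None if feature_subset is None else np.asarray(feature_subset)
    if subset is not None:
        X = X[:, subset]
    model = LogisticRegression(C=C, max_iter=max_iter)
    model.fit(X, y)
    return LinearDecoder(model=model, classes=np.unique(labels),
                         feature_subset=subset)


@dataclass(frozen=True)
class VoxelPartition:
    """Fixed random partition of a population into equal voxel groups."""

    groups: tuple[np.ndarray, ...]

    @classmethod
    def draw(cls, n_neurons: int, n_voxels: int,
             rng: np.random.Generator) -> "VoxelPartition":
        perm = rng.permutation(n_neurons)
        size = n_neurons // n_voxels
        return cls(groups=tuple(perm[i * size:(i + 1) * size]
                                for i in range(n_voxels)))


def voxelize(traces: np.ndarray, partition: VoxelPartition,
             rng: np.random.Generator, noise_var: float = 5.0) -> np.ndarray:
    """Coarse-grain a trace matrix into noisy per-voxel scalars.

    Sums the filtered activity over the neurons of each voxel group,
    averages over time, and adds independent Gaussian noise (variance
    ``noise_var``) -- an fMRI-resolution surrogate signal.
    """
    vals = np.array([traces[:, g].sum(axis=1).mean()
                     for g in partition.groups])
    if noise_var > 0:
        vals = vals + rng.normal(0.0, np.sqrt(noise_var), size=len(vals))
    return vals
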