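"""Rate-coded input patterns and their Poisson realizations.

The input population X consists of ``n_in`` Poisson neurons.  A pattern
activates 25 of them at 100 Hz while the rest stay almost silent (0.1 Hz);
between presentations all input neurons fire at 12.5 Hz so the mean input
rate is roughly constant across phases (25*100 + 175*0.1 = 2517.5 vs
200*12.5 = 2500 spikes/s).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

N_IN = 200
PATTERN_SIZE = 25
RATE_ACTIVE = 100.0
RATE_BACKGROUND = 0.1
RATE_IDLE = 12.5


@dataclass(frozen=True)
class Pattern:
    """One rate pattern: which input neurons fire at the active rate."""

    id: int
    active_set: np.ndarray  # sorted neuron indices, |.| = pattern size
    rate_active: float = RATE_ACTIVE
    rate_background: float = RATE_BACKGROUND

    def rates(self, n_in: int = N_IN) -> np.ndarray:
        """Per-input-neuron rate vector in Hz."""
        r = np.full(n_in, self.rate_background)
        r[self.active_set] = self.rate_active
        return r


@dataclass(frozen=True)
class PatternSet:
    patterns: tuple[Pattern, ...]
    n_in: int = N_IN
    idle_rate: float = RATE_IDLE

    def __len__(self) -> int:
        return len(self.patterns)

    def __getitem__(self, i: int) -> Pattern:
        return self.patterns[i]

    def idle_rates(self) -> np.ndarray:
        return np.full(self.n_in, self.idle_rate)

    def to_text(self) -> str:
        lines = [f"# n_in={self.n_in} idle_rate={self.idle_rate}"]
        for p in self.patterns:
            idx = " ".join(str(i) for i in p.active_set)
            lines.append(f"{p.id}\t{p.rate_active}\t{p.rate_background}\t{idx}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "PatternSet":
        n_in, idle = N_IN, RATE_IDLE
        patterns = []
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for tok in line[1:].split():
                    k, _, v = tok.partition("=")
                    if k == "n_in":
                        n_in = int(v)
                    elif k == "idle_rate":
                        idle = float(v)
                continue
            pid, ra, rb, idx = line.split("\t")
            patterns.append(Pattern(
                id=int(pid),
                active_set=np.array(sorted(int(i) for i in idx.split())),
                rate_active=float(ra), rate_background=float(rb)))
        return cls(patterns=tuple(patterns), n_in=n_in, idle_rate=idle)


def make_patterns(n_patterns: int, rng: np.random.Generator, *,
                  n_in: int = N_IN, pattern_size: int = PATTERN_SIZE,
                  rate_active: float = RATE_ACTIVE,
                  rate_background: float = RATE_BACKGROUND,
                  idle_rate: float = RATE_IDLE) -> PatternSet:
    """Build ``n_patterns`` rate patterns over ``n_in`` input neurons.

    While ``n_patterns * pattern_size <= n_in`` the active sets form a
    disjoint random partition (each input neuron active in at most one
    pattern).  Beyond that -- the capacity sweeps -- disjointness is
    impossible by pigeonhole and independent random subsets are drawn
    instead.
    """
    if n_patterns < 1:
        raise ValueError("n_patterns must be >= 1")
    patterns = []
    if n_patterns * pattern_size <= n_in:
        perm = rng.permutation(n_in)
        for i in range(n_patterns):
            sel = np.sort(perm[i * pattern_size:(i + 1) * pattern_size])
            patterns.append(Pattern(id=i, active_set=sel,
                                    rate_active=rate_active,
                                    rate_background=rate_background))
    else:
        for i in range(n_patterns):
            sel = np.sort(rng.choice(n_in, size=pattern_size, replace=False))
            patterns.append(Pattern(id=i, active_set=sel,
                                    rate_active=rate_active,
                                    rate_background=rate_background))
    return PatternSet(patterns=tuple(patterns), n_in=n_in, idle_rate=idle_rate)


#: Reduced-rate robustness variant of the input statistics.
REDUCED_RATE_PRESET = dict(rate_active=60.0, rate_background=1.0)


def realize(rates: np.ndarray, duration: float, dt: float,
            rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Sample Poisson spike trains on the simulation grid.

    Returns ``(neuron_indices, times_ms)`` sorted by time.  Each neuron
    spikes in a bin of width ``dt`` with probability ``1 - exp(-rate*dt)``,
    matching the simulator's per-step hazard sampling.
    """
    if duration < 0:
        raise ValueError("duration must be non-negative")
    n_steps = int(round(duration / dt))
    n = len(rates)
    p = -np.expm1(-np.asarray(rates) * dt * 1e-3)
    hits = rng.random((n_steps, n)) < p[None, :]
    step, idx = np.nonzero(hits)
    return idx.astype(np.int64), (step + 1) * dt
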