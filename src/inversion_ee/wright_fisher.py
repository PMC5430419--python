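"""Multinomial Wright-Fisher simulation of chromosomal-arrangement frequencies.

Arrangements of one chromosome are mutually exclusive haplotypes, so each
chromosome is a single multiallelic haploid locus carried in 2N copies by N
diploid flies.  Each generation the next cohort's 2*Ne chromosome copies are
drawn from a multinomial over the current (optionally selection-weighted)
frequencies; there is no mutation or migration, so fixation and loss are
absorbing.

The effective size follows the census through a ramp: Ne(t) is a fraction of
the census that interpolates linearly from 10% at the first generation to
30% at the last generation assayed, reflecting the expectation that newly
wild-derived laboratory populations transmit a small fraction of the census
early on and a larger fraction once adapted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class NeTrajectory:
    """Per-generation census and effective sizes over [t0, tend]."""

    generations: tuple[int, ...]
    census: tuple[int, ...]
    ne: tuple[int, ...]
    ne_fraction_start: float = 0.10
    ne_fraction_end: float = 0.30

    def __post_init__(self):
        if len(self.generations) != len(self.census) or len(self.census) != len(self.ne):
            raise ValueError("generations, census and ne must align")
        if any(n < 2 for n in self.ne):
            raise ValueError("effective size below 2")

    @property
    def t0(self) -> int:
        return self.generations[0]

    @property
    def tend(self) -> int:
        return self.generations[-1]

    def ne_at(self, generation: int) -> int:
        return self.ne[self.generations.index(generation)]


@dataclass(frozen=True)
class FitnessSpec:
    """Relative fitnesses w_i = 1 + s_i of the arrangements of one chromosome."""

    w: tuple[float, ...]

    def __post_init__(self):
        if any(wi <= 0 for wi in self.w):
            raise ValueError("fitness values must be positive")

    @classmethod
    def neutral(cls, k: int) -> "FitnessSpec":
        return cls(w=(1.0,) * k)

    @classmethod
    def from_s(cls, s) -> "FitnessSpec":
        return cls(w=tuple(1.0 + np.asarray(s, dtype=float)))


@dataclass
class TrajectoryRealization:
    """Frequencies per generation from one (or a batch of) WF realizations."""

    generations: tuple[int, ...]
    # shape (n_generations, k) or (n_generations, B, k) for batched runs
    frequencies: np.ndarray
    seed: object = field(default=None)

    @property
    def final(self) -> np.ndarray:
        return self.frequencies[-1]


def build_ne_trajectory(
    census: dict[int, int],
    t0: int,
    tend: int,
    f_start: float = 0.10,
    f_end: float = 0.30,
    carry_forward: bool = True,
) -> NeTrajectory:
    """Build the census-linked Ne ramp over generations t0..tend inclusive.

    ``census`` maps generation to census size; with ``carry_forward`` the most
    recent earlier record fills gaps (census records are sparse in practice).
    The Ne fraction interpolates linearly from ``f_start`` at t0 to ``f_end``
    at tend; Ne is the fraction times the census, rounded to nearest.
    """
    if tend <= t0:
        raise ValueError(f"tend ({tend}) must exceed t0 ({t0})")
    gens = list(range(t0, tend + 1))
    filled: list[int] = []
    known = dict(sorted(census.items()))
    earlier = [t for t in known if t <= t0]
    last = known[max(earlier)] if (earlier and carry_forward) else None
    for t in gens:
        if t in known:
            last = known[t]
        elif last is None or not carry_forward:
            raise ValueError(f"no census record for generation {t}")
        filled.append(last)
    span = tend - t0
    ne = []
    for t, n in zip(gens, filled):
        frac = f_start + (f_end - f_start) * (t - t0) / span
        ne_t = int(round(frac * n))
        if ne_t < 2:
            raise ValueError(f"Ne < 2 at generation {t} (census {n}, fraction {frac:.3f})")
        ne.append(ne_t)
    return NeTrajectory(
        generations=tuple(gens),
        census=tuple(filled),
        ne=tuple(ne),
        ne_fraction_start=f_start,
        ne_fraction_end=f_end,
    )


def _check_frequencies(p: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p0 must be a 1-D frequency vector")
    if np.any(p < -tol) or abs(p.sum() - 1.0) > 1e-6:
        raise ValueError(f"frequencies must be non-negative and sum to 1, got {p}")
    return np.clip(p, 0.0, None) / p.sum()


def simulate_trajectory(
    p0,
    ne: NeTrajectory,
    fitness: FitnessSpec | None = None,
    rng: np.random.Generator | None = None,
    n_replicates: int = 1,
) -> TrajectoryRealization:
    """Simulate arrangement frequencies from ne.t0 to ne.tend.

    Each step applies the deterministic genic-selection update
    p'_i = p_i w_i / sum_j p_j w_j, then draws the next generation's
    2*Ne(t+1) chromosome copies from a multinomial over p'.  All arrangements
    of the chromosome evolve jointly in one multinomial; frequencies of 0 and
    1 are absorbing.

    With ``n_replicates`` > 1, B independent realizations are run from the
    same p0 and the frequency array has shape (n_generations, B, k).
    """
    p0 = _check_frequencies(p0)
    k = p0.size
    if fitness is None:
        fitness = FitnessSpec.neutral(k)
    w = np.asarray(fitness.w, dtype=float)
    if w.size != k:
        raise ValueError(f"fitness has {w.size} entries for {k} arrangements")
    if rng is None:
        rng = np.random.default_rng()

    n_gens = len(ne.generations)
    batch = n_replicates > 1
    shape = (n_gens, n_replicates, k) if batch else (n_gens, k)
    freqs = np.empty(shape, dtype=float)
    p = np.broadcast_to(p0, (n_replicates, k)).copy() if batch else p0.copy()
    freqs[0] = p
    for step in range(1, n_gens):
        copies = 2 * ne.ne[step]
        weighted = p * w
        weighted /= weighted.sum(axis=-1, keepdims=True)
        counts = rng.multinomial(copies, weighted)
        p = counts / copies
        freqs[step] = p
    return TrajectoryRealization(generations=ne.generations, frequencies=freqs)


def sample_karyotypes(p, n: int, rng: np.random.Generator) -> np.ndarray:
    """Multinomial sample of ``n`` karyotyped chromosomes from frequencies ``p``.

    Models the terminal scoring step: each assayed male contributes one
    paternal chromosome per arm, so a sample of n males is n independent
    draws from the population's arrangement frequencies.  ``p`` may be a
    batch of frequency vectors (draws one sample per row).
    """
    if n <= 0:
        raise ValueError(f"sample size must be positive, got {n}")
    p = np.asarray(p, dtype=float)
    p = np.clip(p, 0.0, None)
    p = p / p.sum(axis=-1, keepdims=True)
    return rng.multinomial(n, p)
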