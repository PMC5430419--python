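"""Ground-truth synthetic datasets with the study design's structure.

The generator emulates the experimental-evolution design end to end: two
locations x two founding years give four foundations; each foundation
evolves as a single population from its first karyotyped generation until
replication (generation 4), then splits into three replicate populations
that drift (and optionally respond to genic selection) independently under
the census-linked Ne ramp.  Karyotype samples of 65-159 chromosomes are
drawn at each assayed generation, pre-replication generations being sampled
as a single pooled population.  Phenotypes are generated per individual:
control populations fluctuate around stationary trait means while
experimental replicate means converge geometrically toward the control mean
at a programmed per-generation fraction.

Every dataset comes with a ``SyntheticTruth`` record of the programmed
selection coefficients, convergence rates and seeds, sufficient to rerun
any recovery test with no other inputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .karyo_io import CONTROL_LABEL, POOLED_LABEL, validate_karyotype_counts, validate_pheno_assay
from .wright_fisher import FitnessSpec, build_ne_trajectory, sample_karyotypes, simulate_trajectory

#: clinal preset: "north" and "south" initial arrangement frequencies
#: differing by >= 0.3 on two arrangements per chromosome pair of interest
CLINE_NORTH = {
    "O": {"O_ST": 0.55, "O_3+4": 0.25, "O_3+4+7": 0.20},
    "E": {"E_ST": 0.60, "E_1+2": 0.25, "E_1+2+9+12": 0.15},
}
CLINE_SOUTH = {
    "O": {"O_ST": 0.20, "O_3+4": 0.60, "O_3+4+7": 0.20},
    "E": {"E_ST": 0.25, "E_1+2": 0.25, "E_1+2+9+12": 0.50},
}


@dataclass
class TraitSpec:
    """Programmed dynamics of one trait.

    ``convergence`` is the fraction of the remaining offset to the control
    mean lost per generation (0 = flat, 1 = full convergence in one step).
    """

    control_mean: float
    initial_offset: float
    convergence: float = 0.1
    residual_sd: float = 1.0

    def offset_at(self, generations_elapsed: int) -> float:
        return self.initial_offset * (1.0 - self.convergence) ** generations_elapsed


@dataclass
class SyntheticScenario:
    """Study conditions for one synthetic dataset.

    Defaults mirror the design being emulated: 3 replicates per foundation,
    karyotyping at generations 2/6/25 (or 1/8/23 via ``generations``),
    replication at generation 4, constant census of 800 within the 500-1200
    maintenance range, karyotype samples of 65-159 chromosomes, phenotype
    assays of 15-24 pairs.
    """

    foundations: dict = field(default_factory=lambda: {"NORTH": CLINE_NORTH, "SOUTH": CLINE_SOUTH})
    replicates: int = 3
    generations: tuple[int, ...] = (2, 6, 25)
    replication_generation: int = 4
    census: dict | int = 800
    selection: dict = field(default_factory=dict)  # {(chromosome, arrangement): s}
    karyotype_sample_range: tuple[int, int] = (65, 159)
    trait_specs: dict = field(default_factory=dict)  # {trait: TraitSpec}
    assay_generations: tuple[int, ...] = (6, 11, 14, 18, 22, 28)
    assay_sample_range: tuple[int, int] = (15, 24)
    ne_fraction_start: float = 0.10
    ne_fraction_end: float = 0.30
    seed: int = 0

    def census_map(self) -> dict[int, int]:
        if isinstance(self.census, dict):
            return {int(k): int(v) for k, v in self.census.items()}
        return {0: int(self.census)}

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("need >= 1 replicate")
        for fnd, chroms in self.foundations.items():
            for chrom, freqs in chroms.items():
                s = sum(freqs.values())
                if abs(s - 1.0) > 1e-9:
                    raise ValueError(
                        f"initial frequencies for {fnd}/{chrom} sum to {s}, not 1"
                    )
        for spec in self.trait_specs.values():
            if spec.residual_sd < 0:
                raise ValueError("residual SD must be >= 0")


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a generated dataset."""

    selection: dict
    convergence: dict
    seed: int

    def to_json(self, path: str | Path) -> None:
        payload = {
            "selection": {f"{c}:{a}": s for (c, a), s in self.selection.items()},
            "convergence": dict(self.convergence),
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            raw = json.load(fh)
        sel = {tuple(k.split(":", 1)): v for k, v in raw["selection"].items()}
        return cls(selection=sel, convergence=raw["convergence"], seed=raw["seed"])


def _fitness_for(scenario: SyntheticScenario, chromosome: str, labels: list[str]) -> FitnessSpec:
    s = [scenario.selection.get((chromosome, a), 0.0) for a in labels]
    return FitnessSpec.from_s(s)


def generate_karyotype_dataset(
    scenario: SyntheticScenario,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate a full karyotype count table plus its ground truth.

    Shared drift before replication is modeled explicitly: one trajectory
    per foundation runs from the first assayed generation to the
    replication generation, and the replicate trajectories branch from its
    end state, so replicate non-independence matches the real design.
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    t_first, t_last = min(scenario.generations), max(scenario.generations)
    t_split = scenario.replication_generation
    if t_split < t_first:
        raise ValueError("replication generation precedes first assayed generation")
    census = scenario.census_map()
    rows = []
    lo, hi = scenario.karyotype_sample_range
    for fnd, chroms in scenario.foundations.items():
        for chrom, freqs in chroms.items():
            labels = sorted(freqs)
            p0 = np.array([freqs[a] for a in labels], dtype=float)
            fit = _fitness_for(scenario, chrom, labels)
            ne_all = build_ne_trajectory(
                census, t_first, t_last,
                f_start=scenario.ne_fraction_start, f_end=scenario.ne_fraction_end,
            )
            # shared pre-replication trajectory t_first -> t_split
            shared_ne = _slice_ne(ne_all, t_first, t_split)
            shared = simulate_trajectory(p0, shared_ne, fit, rng=rng)
            p_split = shared.final
            for gen in scenario.generations:
                if gen <= t_split:
                    i = shared.generations.index(gen)
                    n = int(rng.integers(lo, hi + 1))
                    counts = sample_karyotypes(shared.frequencies[i], n, rng)
                    rows += _rows(fnd, POOLED_LABEL, gen, chrom, labels, counts)
            later = [g for g in scenario.generations if g > t_split]
            for r in range(1, scenario.replicates + 1):
                rep_ne = _slice_ne(ne_all, t_split, t_last)
                traj = simulate_trajectory(p_split, rep_ne, fit, rng=rng)
                for gen in later:
                    i = traj.generations.index(gen)
                    n = int(rng.integers(lo, hi + 1))
                    counts = sample_karyotypes(traj.frequencies[i], n, rng)
                    rows += _rows(fnd, f"R{r}", gen, chrom, labels, counts)
    table = validate_karyotype_counts(pd.DataFrame(rows))
    truth = SyntheticTruth(
        selection=dict(scenario.selection),
        convergence={t: spec.convergence for t, spec in scenario.trait_specs.items()},
        seed=scenario.seed,
    )
    return table, truth


def _slice_ne(ne, t0: int, tend: int):
    i0 = ne.generations.index(t0)
    i1 = ne.generations.index(tend)
    from .wright_fisher import NeTrajectory

    return NeTrajectory(
        generations=ne.generations[i0:i1 + 1],
        census=ne.census[i0:i1 + 1],
        ne=ne.ne[i0:i1 + 1],
        ne_fraction_start=ne.ne_fraction_start,
        ne_fraction_end=ne.ne_fraction_end,
    )


def _rows(fnd, rep, gen, chrom, labels, counts):
    return [
        {
            "foundation": fnd, "replicate": rep, "generation": gen,
            "chromosome": chrom, "arrangement": a, "count": int(c),
        }
        for a, c in zip(labels, counts)
    ]


DEFAULT_TRAITS = {
    "F1-7": TraitSpec(control_mean=180.0, initial_offset=-60.0, convergence=0.10, residual_sd=25.0),
    "A1R": TraitSpec(control_mean=4.0, initial_offset=2.0, convergence=0.10, residual_sd=1.0),
    "RF": TraitSpec(control_mean=60.0, initial_offset=12.0, convergence=0.08, residual_sd=8.0),
}


def generate_phenotype_dataset(
    scenario: SyntheticScenario,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate experimental + synchronous control phenotype assays.

    Control individuals are drawn around the stationary control mean at
    every assayed generation; an experimental replicate's mean deviates by
    initial_offset * (1 - convergence)^(t - t_first) and individuals add
    Gaussian residual noise.  Replicate offsets get a small lognormal
    proportionality factor so programmed initial differences vary across
    replicates (as founder sampling would produce).
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed + 1)
    specs = scenario.trait_specs or DEFAULT_TRAITS
    gens = scenario.assay_generations
    t_first = min(gens)
    lo, hi = scenario.assay_sample_range
    rows = []
    for trait, spec in specs.items():
        for gen in gens:
            n_ctrl = int(rng.integers(lo, hi + 1))
            for i in range(n_ctrl):
                rows.append({
                    "foundation": CONTROL_LABEL, "replicate": "TA", "generation": gen,
                    "trait": trait, "individual_id": f"c{gen}_{i}",
                    "value": rng.normal(spec.control_mean, spec.residual_sd),
                })
    for fnd in scenario.foundations:
        for r in range(1, scenario.replicates + 1):
            rep_factor = {
                trait: float(np.exp(rng.normal(0.0, 0.15))) for trait in specs
            }
            for trait, spec in specs.items():
                for gen in gens:
                    mean = spec.control_mean + rep_factor[trait] * spec.offset_at(gen - t_first)
                    n = int(rng.integers(lo, hi + 1))
                    for i in range(n):
                        rows.append({
                            "foundation": fnd, "replicate": f"R{r}", "generation": gen,
                            "trait": trait, "individual_id": f"{fnd}{r}_{gen}_{i}",
                            "value": rng.normal(mean, spec.residual_sd),
                        })
    return validate_pheno_assay(pd.DataFrame(rows))
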