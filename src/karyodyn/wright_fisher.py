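"""Forward-time Wright–Fisher simulation of karyotype frequencies.

Each discrete generation, every adult contributes to its sex's gamete
pool in proportion to fitness × its gamete genotype distribution; the
pools are normalized and ``population_size`` zygotes are formed by
independently drawing one egg and one sperm per zygote.  Zygote sex is
emergent from the X count of the sampled gametes (an XY-bearing egg plus
an X sperm makes an XXY daughter).  An empty pool — no fit individuals
of one sex — terminates the run with an extinction flag.

``deterministic_run`` iterates the same recursion on expected
frequencies (the infinite-population limit) and serves as an analytic
oracle for the stochastic engine.

The quantity of interest is the Y^S share: the fraction of truncated
Y^S chromosomes among all Y-type chromosomes in the population, pooled
over both sexes (per-sex shares are also recorded).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from .genotypes import (
    FEMALE,
    MALE,
    FitnessParams,
    KaryoGenotype,
    female_fitness,
    format_genotype,
    male_fitness,
    parse_genotype,
    sex_of,
)
from .meiosis import GameteDistribution, female_gametes, male_gametes
from .observations import OBSERVED_FEMALE_FREQS, OBSERVED_MALE_FREQS

__all__ = [
    "SimConfig",
    "PopulationState",
    "Trajectory",
    "gamete_pools",
    "step",
    "run",
    "deterministic_run",
    "ys_share",
]

GenotypeWeights = Mapping[KaryoGenotype, float]


def _normalized(dist: GenotypeWeights, what: str) -> Dict[KaryoGenotype, float]:
    total = float(sum(dist.values()))
    if total <= 0:
        raise ValueError(f"{what} has non-positive total weight")
    if any(v < 0 for v in dist.values()):
        raise ValueError(f"{what} has negative entries")
    return {g: v / total for g, v in dist.items() if v > 0}


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one simulation.

    Initial distributions default to the observed Seychelles karyotype
    frequencies (females sum to 1; the printed male values sum to 0.98
    and are renormalized here).
    """

    population_size: int = 100
    generations: int = 200
    params: FitnessParams = field(default_factory=FitnessParams)
    initial_female_dist: Mapping[KaryoGenotype, float] = field(
        default_factory=lambda: dict(OBSERVED_FEMALE_FREQS)
    )
    initial_male_dist: Mapping[KaryoGenotype, float] = field(
        default_factory=lambda: dict(OBSERVED_MALE_FREQS)
    )
    seed: int = 0
    replicates: int = 1
    splits: str = "all_nonempty"

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be at least 2")
        if self.generations < 0:
            raise ValueError("generations must be non-negative")
        f = _normalized(self.initial_female_dist, "initial_female_dist")
        m = _normalized(self.initial_male_dist, "initial_male_dist")
        for g in f:
            if sex_of(g) != FEMALE:
                raise ValueError(f"initial female distribution contains {g}")
        for g in m:
            if sex_of(g) != MALE:
                raise ValueError(f"initial male distribution contains {g}")
        object.__setattr__(self, "initial_female_dist", f)
        object.__setattr__(self, "initial_male_dist", m)

    # --- YAML round-trip ---------------------------------------------------

    def to_yaml(self) -> str:
        doc = {
            "population_size": self.population_size,
            "generations": self.generations,
            "seed": self.seed,
            "replicates": self.replicates,
            "splits": self.splits,
            "params": {
                "s": self.params.s,
                "y": self.params.y,
                "h": self.params.h,
                "h_prime": self.params.h_prime,
                "h_dblprime": self.params.h_dblprime,
                "m3": self.params.m3,
            },
            "initial_female_dist": {
                format_genotype(g): p for g, p in self.initial_female_dist.items()
            },
            "initial_male_dist": {
                format_genotype(g): p for g, p in self.initial_male_dist.items()
            },
        }
        return yaml.safe_dump(doc, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "SimConfig":
        doc = yaml.safe_load(text)
        kwargs = dict(doc)
        if "params" in kwargs:
            kwargs["params"] = FitnessParams(**kwargs["params"])
        for key in ("initial_female_dist", "initial_male_dist"):
            if key in kwargs:
                kwargs[key] = {parse_genotype(k): v for k, v in kwargs[key].items()}
        return cls(**kwargs)


@dataclass(frozen=True)
class PopulationState:
    """Genotype counts of one generation, partitioned by sex."""

    generation: int
    females: Mapping[KaryoGenotype, int]
    males: Mapping[KaryoGenotype, int]

    @property
    def size(self) -> int:
        return sum(self.females.values()) + sum(self.males.values())

    @property
    def extinct(self) -> bool:
        return self.size == 0


def _pool(
    weights: GenotypeWeights,
    fitness_fn,
    gametes_fn,
) -> GameteDistribution:
    """Fitness-weighted, normalized gamete pool; empty dict if no contribution."""
    pool: Dict[KaryoGenotype, float] = {}
    for genotype, w in weights.items():
        if w <= 0:
            continue
        fit = fitness_fn(genotype)
        if fit <= 0:
            continue
        contrib = w * fit
        for gamete, p in gametes_fn(genotype).items():
            pool[gamete] = pool.get(gamete, 0.0) + contrib * p
    total = sum(pool.values())
    if total <= 0:
        return {}
    return {g: v / total for g, v in pool.items()}


def gamete_pools(
    state: PopulationState,
    params: FitnessParams,
    splits: str = "all_nonempty",
) -> Tuple[GameteDistribution, GameteDistribution]:
    """Normalized egg and sperm pools of a population state.

    Individuals with fitness 0 (XX females, Y^S-only males, ...) contribute
    nothing.  An empty dict marks an exhausted pool — impending extinction.
    """
    egg = _pool(
        state.females,
        lambda g: female_fitness(g, params),
        female_gametes,
    )
    sperm = _pool(
        state.males,
        lambda g: male_fitness(g, params),
        lambda g: male_gametes(g, splits),
    )
    return egg, sperm


def _zygote_distribution(
    egg_pool: GameteDistribution, sperm_pool: GameteDistribution
) -> Dict[KaryoGenotype, float]:
    zygotes: Dict[KaryoGenotype, float] = {}
    for egg, pe in egg_pool.items():
        for sperm, ps in sperm_pool.items():
            z = egg + sperm
            zygotes[z] = zygotes.get(z, 0.0) + pe * ps
    return zygotes


def step(
    state: PopulationState,
    config: SimConfig,
    rng: np.random.Generator,
) -> PopulationState:
    """One generation: gamete pools → multinomial zygote sampling.

    Returns an extinct (empty) state if either pool is empty.
    """
    egg_pool, sperm_pool = gamete_pools(state, config.params, config.splits)
    if not egg_pool or not sperm_pool:
        return PopulationState(state.generation + 1, {}, {})
    zygotes = _zygote_distribution(egg_pool, sperm_pool)
    genotypes = list(zygotes)
    probs = np.fromiter((zygotes[g] for g in genotypes), dtype=float)
    probs /= probs.sum()
    counts = rng.multinomial(config.population_size, probs)
    females: Dict[KaryoGenotype, int] = {}
    males: Dict[KaryoGenotype, int] = {}
    for genotype, c in zip(genotypes, counts):
        if c == 0:
            continue
        (females if genotype.n_x == 2 else males)[genotype] = int(c)
    return PopulationState(state.generation + 1, females, males)


def _sample_counts(
    dist: GenotypeWeights, n: int, rng: np.random.Generator
) -> Dict[KaryoGenotype, int]:
    genotypes = list(dist)
    probs = np.fromiter((dist[g] for g in genotypes), dtype=float)
    probs /= probs.sum()
    draws = rng.multinomial(n, probs)
    return {g: int(c) for g, c in zip(genotypes, draws) if c > 0}


def initial_state(config: SimConfig, rng: np.random.Generator) -> PopulationState:
    """Generation 0: an even sex ratio, genotypes drawn from the initial
    distributions (the observed strain frequencies by default)."""
    n_f = config.population_size // 2
    n_m = config.population_size - n_f
    return PopulationState(
        0,
        _sample_counts(config.initial_female_dist, n_f, rng),
        _sample_counts(config.initial_male_dist, n_m, rng),
    )


# --- Y^S share -------------------------------------------------------------


def ys_share(weights: GenotypeWeights) -> float:
    """Fraction of Y^S among all Y-type chromosomes; NaN when none exist."""
    num = 0.0
    den = 0.0
    for genotype, w in weights.items():
        num += w * genotype.n_ys
        den += w * genotype.n_ytype
    if den <= 0:
        return math.nan
    return num / den


def _pooled(state: PopulationState) -> Dict[KaryoGenotype, float]:
    merged: Dict[KaryoGenotype, float] = dict(state.females)
    for g, c in state.males.items():
        merged[g] = merged.get(g, 0.0) + c
    return merged


# --- trajectories ----------------------------------------------------------


@dataclass
class Trajectory:
    """Per-generation karyotype frequencies and derived Y^S shares.

    ``female_freqs[t]`` / ``male_freqs[t]`` are within-sex frequency
    distributions at generation ``t``; ``ys_shares[t]`` pools both sexes.
    A run that exhausts a gamete pool is truncated at the last living
    generation and flagged extinct.
    """

    female_freqs: List[Dict[KaryoGenotype, float]]
    male_freqs: List[Dict[KaryoGenotype, float]]
    ys_shares: np.ndarray
    ys_shares_female: np.ndarray
    ys_shares_male: np.ndarray
    extinct: bool = False
    extinction_generation: Optional[int] = None

    @property
    def n_generations(self) -> int:
        """Index of the last recorded generation."""
        return len(self.ys_shares) - 1

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: generation, sex, genotype, frequency."""
        rows = []
        for t, (ff, mf) in enumerate(zip(self.female_freqs, self.male_freqs)):
            for sx, freqs in ((FEMALE, ff), (MALE, mf)):
                for g in sorted(freqs):
                    rows.append(
                        {
                            "generation": t,
                            "sex": sx,
                            "genotype": format_genotype(g),
                            "frequency": freqs[g],
                        }
                    )
        return pd.DataFrame(rows, columns=["generation", "sex", "genotype", "frequency"])

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "generation": np.arange(len(self.ys_shares)),
                "ys_share": self.ys_shares,
                "ys_share_female": self.ys_shares_female,
                "ys_share_male": self.ys_shares_male,
            }
        )

    @classmethod
    def from_frames(
        cls,
        long: pd.DataFrame,
        summary: pd.DataFrame,
        extinct: bool = False,
        extinction_generation: Optional[int] = None,
    ) -> "Trajectory":
        n_gen = int(summary["generation"].max()) + 1
        female_freqs: List[Dict[KaryoGenotype, float]] = [{} for _ in range(n_gen)]
        male_freqs: List[Dict[KaryoGenotype, float]] = [{} for _ in range(n_gen)]
        for row in long.itertuples(index=False):
            target = female_freqs if row.sex == FEMALE else male_freqs
            target[int(row.generation)][parse_genotype(row.genotype)] = float(
                row.frequency
            )
        return cls(
            female_freqs,
            male_freqs,
            summary["ys_share"].to_numpy(dtype=float),
            summary["ys_share_female"].to_numpy(dtype=float),
            summary["ys_share_male"].to_numpy(dtype=float),
            extinct=extinct,
            extinction_generation=extinction_generation,
        )


def _freqs(counts: Mapping[KaryoGenotype, float]) -> Dict[KaryoGenotype, float]:
    total = sum(counts.values())
    if total <= 0:
        return {}
    return {g: c / total for g, c in counts.items()}


def run(config: SimConfig, rng: Optional[np.random.Generator] = None) -> Trajectory:
    """One stochastic replicate of ``config.generations`` generations."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    state = initial_state(config, rng)
    female_freqs = [_freqs(state.females)]
    male_freqs = [_freqs(state.males)]
    shares = [ys_share(_pooled(state))]
    shares_f = [ys_share(state.females)]
    shares_m = [ys_share(state.males)]
    extinct = False
    extinction_generation: Optional[int] = None
    for _ in range(config.generations):
        state = step(state, config, rng)
        if state.extinct:
            extinct = True
            extinction_generation = state.generation
            break
        female_freqs.append(_freqs(state.females))
        male_freqs.append(_freqs(state.males))
        shares.append(ys_share(_pooled(state)))
        shares_f.append(ys_share(state.females))
        shares_m.append(ys_share(state.males))
    return Trajectory(
        female_freqs,
        male_freqs,
        np.asarray(shares, dtype=float),
        np.asarray(shares_f, dtype=float),
        np.asarray(shares_m, dtype=float),
        extinct=extinct,
        extinction_generation=extinction_generation,
    )


def deterministic_run(config: SimConfig) -> Trajectory:
    """Infinite-population limit: iterate expected frequencies exactly.

    Generation 0 weights the two initial distributions 1/2 each (the even
    sex ratio of the stochastic start); afterwards the sex ratio evolves
    freely with the zygote distribution.
    """
    joint: Dict[KaryoGenotype, float] = {}
    for g, p in config.initial_female_dist.items():
        joint[g] = joint.get(g, 0.0) + 0.5 * p
    for g, p in config.initial_male_dist.items():
        joint[g] = joint.get(g, 0.0) + 0.5 * p

    def by_sex(dist: GenotypeWeights) -> Tuple[Dict, Dict]:
        f = {g: p for g, p in dist.items() if g.n_x == 2}
        m = {g: p for g, p in dist.items() if g.n_x == 1}
        return f, m

    female_freqs = []
    male_freqs = []
    shares = []
    shares_f = []
    shares_m = []
    extinct = False
    extinction_generation: Optional[int] = None

    f, m = by_sex(joint)
    female_freqs.append(_freqs(f))
    male_freqs.append(_freqs(m))
    shares.append(ys_share(joint))
    shares_f.append(ys_share(f))
    shares_m.append(ys_share(m))

    for t in range(config.generations):
        f, m = by_sex(joint)
        state = PopulationState(t, f, m)
        egg_pool, sperm_pool = gamete_pools(state, config.params, config.splits)
        if not egg_pool or not sperm_pool:
            extinct = True
            extinction_generation = t + 1
            break
        joint = _zygote_distribution(egg_pool, sperm_pool)
        f, m = by_sex(joint)
        female_freqs.append(_freqs(f))
        male_freqs.append(_freqs(m))
        shares.append(ys_share(joint))
        shares_f.append(ys_share(f))
        shares_m.append(ys_share(m))

    return Trajectory(
        female_freqs,
        male_freqs,
        np.asarray(shares, dtype=float),
        np.asarray(shares_f, dtype=float),
        np.asarray(shares_m, dtype=float),
        extinct=extinct,
        extinction_generation=extinction_generation,
    )


def replicate_seeds(root_seed: int, n: int) -> List[np.random.SeedSequence]:
    """Deterministic child seeds, one per replicate."""
    return [np.random.SeedSequence([int(root_seed), r]) for r in range(n)]


def run_replicates(config: SimConfig) -> List[Trajectory]:
    """``config.replicates`` independent runs with derived child seeds."""
    out = []
    for ss in replicate_seeds(config.seed, config.replicates):
        out.append(run(config, np.random.default_rng(ss)))
    return out
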