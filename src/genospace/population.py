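"""Fisher-Wright evolution of polymorphic populations on a genotype network.

A population of P networks (default 100) starts as P copies of a single
demand-viable founder and undergoes discrete generations of mutation and
selection: every individual receives exactly one reaction change per
generation (alternating additions and deletions per lineage, so each
individual's size stays in {N, N+1}), and the next generation is formed by
sampling P individuals uniformly with replacement from the demand-viable
post-mutation individuals.  A mutant that lost demand-viability persists for
that generation but has selection weight zero, operationalizing "could not
be chosen".  All demand-viable genotypes are selectively equivalent — the
population drifts neutrally on the genotype network.

Per generation the mean pairwise genotype distance (population diversity) is
recorded; optionally, every g-th generation the one-mutant neighborhood of
every member is evaluated and the distinct novel phenotype vectors are
accumulated, giving the population-level cumulative novelty count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fba import Genotype, get_model
from .genotype_space import as_demand
from .universe import ReactionUniverse
from .walks import cumulative_novel, neighborhood_phenotypes

__all__ = [
    "PopulationState",
    "PopulationSeries",
    "evolve_population",
    "population_diversity",
    "population_cumulative_novel",
]


@dataclass
class PopulationState:
    """One generation of an evolving population."""

    generation: int
    genotypes: list[Genotype]
    diversity: float
    novel: frozenset[bytes] | None = None  # union over members, if sampled

    @property
    def size(self) -> int:
        return len(self.genotypes)


@dataclass
class PopulationSeries:
    """The full trajectory of a population simulation."""

    demand: tuple[str, ...]
    states: list[PopulationState] = field(default_factory=list)
    n_resampled_generations: int = 0

    @property
    def diversity(self) -> np.ndarray:
        return np.array([s.diversity for s in self.states])

    @property
    def sampled_generations(self) -> list[int]:
        return [s.generation for s in self.states if s.novel is not None]


def population_diversity(state: PopulationState | list[Genotype]) -> float:
    """Mean pairwise genotype distance over all unordered member pairs."""
    genotypes = state.genotypes if isinstance(state, PopulationState) else state
    if len(genotypes) < 2:
        raise ValueError("diversity needs a population of >= 2")
    bits = np.array([g.bits for g in genotypes], dtype=np.int32)
    sizes = bits.sum(axis=1)
    shared = bits @ bits.T
    denom = sizes[:, None] + sizes[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        d = 1.0 - 2.0 * shared / denom
    d = np.nan_to_num(d, nan=0.0)
    iu = np.triu_indices(len(genotypes), k=1)
    return float(d[iu].mean())


def population_cumulative_novel(series: PopulationSeries) -> np.ndarray:
    """Running count of distinct novel phenotypes over sampled generations."""
    sets = [s.novel for s in series.states if s.novel is not None]
    return cumulative_novel(sets)


def evolve_population(founder: Genotype, universe: ReactionUniverse, demand,
                      P: int, generations: int, rng: np.random.Generator,
                      mutate: bool = True,
                      neighborhood_stride: int | None = None,
                      max_resample: int = 100) -> PopulationSeries:
    """Run a Fisher-Wright simulation from P copies of a viable founder.

    ``mutate=False`` disables mutation (a drift control: the population stays
    identical to the founder).  ``neighborhood_stride=g`` evaluates every
    member's one-mutant neighborhood at generation 0 and every g-th
    generation.  If a generation produces zero viable mutants its mutations
    are redrawn (counted in ``n_resampled_generations``).
    """
    demand = as_demand(demand)
    model = get_model(universe)
    if not model.meets_demand(founder, demand):
        raise ValueError("founder is not viable on the demand")
    if P < 1 or generations < 0:
        raise ValueError("P must be >= 1 and generations >= 0")
    n0 = founder.size
    series = PopulationSeries(demand=tuple(demand))

    def snapshot(gen: int, members: list[Genotype]) -> None:
        novel = None
        if neighborhood_stride and gen % neighborhood_stride == 0:
            union: set[bytes] = set()
            for g in members:
                union |= neighborhood_phenotypes(g, universe, demand).novel
            novel = frozenset(union)
        diversity = population_diversity(members) if P >= 2 else 0.0
        series.states.append(PopulationState(gen, list(members), diversity, novel))

    members = [founder] * P
    snapshot(0, members)
    for gen in range(1, generations + 1):
        if not mutate:
            snapshot(gen, members)
            continue
        for attempt in range(max_resample):
            mutants: list[Genotype] = []
            viable: list[int] = []
            for i, g in enumerate(members):
                adding = g.size == n0
                pool = np.flatnonzero(~g.bits if adding else g.bits)
                idx = int(pool[rng.integers(len(pool))])
                mutant = g.with_bit(idx, adding)
                mutants.append(mutant)
                if model.meets_demand(mutant, demand):
                    viable.append(i)
            if viable:
                break
            series.n_resampled_generations += 1
        else:
            raise RuntimeError(
                f"no viable mutant in generation {gen} after {max_resample} redraws")
        chosen = rng.integers(len(viable), size=P)
        members = [mutants[viable[c]] for c in chosen]
        snapshot(gen, members)
    return series
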