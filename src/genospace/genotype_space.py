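"""Distances, random viable networks, essentiality and the closed-form model.

The genotype distance between two metabolic networks is the fraction of
reactions in which they differ,

    D = 1 - 2 R_c / (N_1 + N_2),

with R_c the number of shared reactions; for equal sizes this is 1 - R_c/N.

Random demand-viable networks of a target size N are generated by starting
from the full universe and deleting reactions in uniformly random order,
rolling back any deletion that breaks viability on the demanded sources
(a failed reaction is permanently retired as a candidate, which is exact:
viability is monotone in the reaction set).  Running the same procedure to
exhaustion yields a *minimal* network, one in which every reaction is
essential.  Reactions appearing in every sampled minimal network for a demand
are *superessential*; their count R_SE bounds how far phenotype-preserving
paths can travel (D_max = 1 - R_SE/N for networks of equal size N).

Robustness is the fraction of non-essential reactions, rho = 1 - R_ess/N.
Empirically R_ess declines linearly with N, R_ess = N_min (1+m) - N m, giving
the closed-form prediction

    rho = 1 + m - (N_min / N) (1 + m).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .fba import Genotype, get_model
from .universe import ReactionUniverse

__all__ = [
    "Demand",
    "MinimalNetStats",
    "EssentialDeclineFit",
    "distance",
    "random_demand",
    "random_viable_network",
    "minimal_network",
    "essential_reactions",
    "superessential_reactions",
    "robustness",
    "fit_essential_decline",
    "predicted_robustness",
    "predicted_dmax",
]


@dataclass(frozen=True)
class Demand:
    """The environmental demand: sole sources viability is required on."""

    sources: tuple[str, ...]

    @property
    def S(self) -> int:
        return len(self.sources)

    def __iter__(self):
        return iter(self.sources)

    def __len__(self) -> int:
        return len(self.sources)


def as_demand(demand) -> Demand:
    if isinstance(demand, Demand):
        return demand
    return Demand(tuple(demand))


def random_demand(universe: ReactionUniverse, S: int,
                  rng: np.random.Generator) -> Demand:
    """Draw S distinct candidate sources uniformly at random."""
    if not 1 <= S <= len(universe.sources):
        raise ValueError(f"S={S} outside 1..{len(universe.sources)}")
    idx = rng.choice(len(universe.sources), size=S, replace=False)
    return Demand(tuple(universe.sources[i] for i in sorted(idx)))


def distance(g1: Genotype, g2: Genotype) -> float:
    """Genotype distance D = 1 - 2 R_c / (N_1 + N_2); 0 for two empty networks."""
    if g1.universe_key != g2.universe_key:
        raise ValueError("genotypes from different universes are incomparable")
    n1 = g1.size
    n2 = g2.size
    if n1 + n2 == 0:
        return 0.0
    rc = int(np.count_nonzero(g1.bits & g2.bits))
    return 1.0 - 2.0 * rc / (n1 + n2)


def _reduce(universe: ReactionUniverse, demand: Demand,
            rng: np.random.Generator, target: int | None,
            start: Genotype | None = None) -> Genotype:
    model = get_model(universe)
    genotype = start if start is not None else Genotype.full(universe)
    if not model.meets_demand(genotype, demand):
        raise ValueError("starting network is not viable on the demand")
    bits = genotype.bits.copy()
    order = rng.permutation(np.flatnonzero(bits))
    size = int(bits.sum())
    for idx in order:
        if target is not None and size <= target:
            return Genotype(bits, universe.key)
        bits[idx] = False
        if model.meets_demand(Genotype(bits, universe.key), demand):
            size -= 1
        else:
            bits[idx] = True  # essential here (and in every subset): retire it
    if target is not None and size > target:
        raise ValueError(
            f"target size {target} below the minimal regime (stuck at {size})")
    return Genotype(bits, universe.key)


def random_viable_network(universe: ReactionUniverse, demand, N: int,
                          rng: np.random.Generator) -> Genotype:
    """A random demand-viable network of exactly N reactions.

    Reactions are deleted from the full universe in uniformly random order;
    a deletion breaking demand-viability is rolled back and that reaction is
    retired from the candidate list.
    """
    demand = as_demand(demand)
    if N > universe.size:
        raise ValueError(f"N={N} exceeds universe size {universe.size}")
    return _reduce(universe, demand, rng, target=N)


def minimal_network(universe: ReactionUniverse, demand,
                    rng: np.random.Generator, verify: bool = True,
                    start: Genotype | None = None) -> Genotype:
    """A random minimal demand-viable network (every reaction essential).

    Monotonicity of viability makes the single randomized deletion pass exact;
    ``verify`` re-checks the single-deletion postcondition explicitly.
    """
    demand = as_demand(demand)
    genotype = _reduce(universe, demand, rng, target=None, start=start)
    if verify:
        model = get_model(universe)
        for idx in np.flatnonzero(genotype.bits):
            if model.meets_demand(genotype.with_bit(idx, False), demand):
                raise AssertionError(
                    f"minimality violated: {universe.reactions[idx].id} removable")
    return genotype


def essential_reactions(genotype: Genotype, universe: ReactionUniverse,
                        demand, full_phenotype: bool = False) -> frozenset[str]:
    """Reactions whose deletion destroys viability on a protected source.

    By default the protected sources are the demanded ones (what minimal-
    network generation enforces).  With ``full_phenotype=True`` the literal
    definition is used instead: any source the genotype is currently viable
    on counts, so a deletion losing even an un-demanded source is essential.
    """
    model = get_model(universe)
    if full_phenotype:
        protected = [s for s in universe.sources if model.viable_on(genotype, s)]
    else:
        protected = list(as_demand(demand))
    out = []
    for idx in np.flatnonzero(genotype.bits):
        mutant = genotype.with_bit(idx, False)
        if not all(model.viable_on(mutant, s) for s in protected):
            out.append(universe.reactions[idx].id)
    return frozenset(out)


def robustness(genotype: Genotype, universe: ReactionUniverse, demand,
               full_phenotype: bool = False) -> float:
    """Fraction of non-essential reactions, rho = 1 - R_ess / N."""
    n = genotype.size
    if n == 0:
        raise ValueError("robustness undefined for the empty network")
    ess = essential_reactions(genotype, universe, demand,
                              full_phenotype=full_phenotype)
    return 1.0 - len(ess) / n


@dataclass
class MinimalNetStats:
    """Replicate statistics of minimal networks under one demand."""

    demand: Demand
    sizes: list[int]
    superessential: frozenset[str]
    networks: list[Genotype] = field(default_factory=list, repr=False)
    pairwise_distances: list[float] = field(default_factory=list, repr=False)
    m: float | None = None

    @property
    def n_min(self) -> float:
        """Mean minimal-network size."""
        return float(np.mean(self.sizes))

    @property
    def r_se(self) -> int:
        """Number of superessential reactions (intersection estimate)."""
        return len(self.superessential)

    @property
    def d_avg(self) -> float:
        """Mean pairwise genotype distance among replicate minimal networks."""
        return float(np.mean(self.pairwise_distances))


def superessential_reactions(universe: ReactionUniverse, demand,
                             n_replicates: int,
                             rng: np.random.Generator,
                             verify: bool = False) -> MinimalNetStats:
    """Estimate the superessential set from replicate minimal networks.

    R_SE is the size of the intersection of ``n_replicates`` independently
    sampled minimal networks — an estimate that is monotonically
    non-increasing in the number of replicates.
    """
    demand = as_demand(demand)
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    networks = [minimal_network(universe, demand, rng, verify=verify)
                for _ in range(n_replicates)]
    common = networks[0].bits.copy()
    for g in networks[1:]:
        common &= g.bits
    superessential = frozenset(universe.reactions[i].id
                               for i in np.flatnonzero(common))
    dists = [distance(networks[i], networks[j])
             for i in range(len(networks)) for j in range(i + 1, len(networks))]
    return MinimalNetStats(demand=demand,
                           sizes=[g.size for g in networks],
                           superessential=superessential,
                           networks=networks,
                           pairwise_distances=dists)


@dataclass
class EssentialDeclineFit:
    """Least-squares fit of R_ess against N: R_ess = intercept - m N."""

    m: float
    intercept: float
    stderr: float
    ci95: tuple[float, float]
    r_squared: float


def fit_essential_decline(samples: Sequence[tuple[float, float]]
                          ) -> EssentialDeclineFit:
    """Fit the decline rate m of essential-reaction count with network size.

    ``samples`` are (N, R_ess) pairs at a fixed demand; m is the negated
    least-squares slope, with a 95% confidence interval from the usual
    t-based standard error.
    """
    arr = np.asarray(samples, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or len(arr) < 2:
        raise ValueError("need >= 2 (N, R_ess) samples")
    n_vals, r_vals = arr[:, 0], arr[:, 1]
    if np.ptp(n_vals) == 0:
        raise ValueError("all N identical: slope undefined")
    fit = stats.linregress(n_vals, r_vals)
    m = -fit.slope
    if m < 0:
        warnings.warn(f"fitted decline rate m={m:.4g} is negative",
                      stacklevel=2)
    dof = len(arr) - 2
    half = (stats.t.ppf(0.975, dof) * fit.stderr) if dof > 0 else np.inf
    return EssentialDeclineFit(m=m, intercept=fit.intercept,
                               stderr=fit.stderr,
                               ci95=(m - half, m + half),
                               r_squared=fit.rvalue ** 2)


def predicted_robustness(N: float, N_min: float, m: float) -> float:
    """Closed-form robustness: rho = 1 + m - (N_min / N)(1 + m)."""
    if N <= 0:
        raise ValueError("N must be positive")
    if N < N_min:
        warnings.warn(f"N={N} below N_min={N_min}: outside the model domain",
                      stacklevel=2)
    return 1.0 + m - (N_min / N) * (1.0 + m)


def predicted_dmax(N: float, R_SE: float) -> float:
    """Maximal equal-size genotype distance: D_max = 1 - R_SE / N."""
    if N <= 0:
        raise ValueError("N must be positive")
    return 1.0 - R_SE / N
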