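"""Phenotype-preserving random walks and one-mutant neighborhood novelty.

A *neutral walk* is a sequence of accepted single-reaction changes (additions
or deletions) through genotype space, every visited network remaining viable
on the demanded sole sources.  Accepted mutations alternate between additions
and deletions so the network size stays in the narrow interval {N, N+1}.  In
*forced* mode two extra constraints maximize the distance travelled from the
starting network: additions may never re-introduce a reaction of the initial
network, and no accepted step may decrease the distance to it.  The maximal
distance D_max reached is reported over visited states of the same size N as
the start (the equal-size distance form 1 - R_c/N).

A genotype's (1-mutant) *neighborhood* consists of all U single-reaction
variants.  Each neighbor is classified as inviable (fails the demand), same
(identical full phenotype vector), or novel (meets the demand with a
different phenotype — it gained viability on at least one new source).  The
set of distinct novel phenotype vectors per neighborhood drives the novelty
statistics: the fraction unique to an evolved network's neighborhood versus
the start's, and the cumulative number of distinct novel phenotypes seen
along a walk.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .fba import Genotype, get_model, phenotype_key
from .genotype_space import as_demand, distance
from .universe import ReactionUniverse

__all__ = [
    "NeighborhoodResult",
    "WalkRecord",
    "neutral_walk",
    "neighborhood_phenotypes",
    "unique_fraction",
    "cumulative_novel",
]


@dataclass
class NeighborhoodResult:
    """Classification of all U one-mutant neighbors of a focal genotype."""

    novel: frozenset[bytes]
    n_inviable: int
    n_same: int
    n_novel: int

    @property
    def n_neighbors(self) -> int:
        return self.n_inviable + self.n_same + self.n_novel


@dataclass
class WalkRecord:
    """Trajectory and statistics of one neutral walk."""

    start: Genotype
    demand: tuple[str, ...]
    forced: bool
    steps: list[tuple[int, str, str]] = field(default_factory=list)  # (i, op, rxn)
    distances: list[float] = field(default_factory=list)
    d_max: float = 0.0
    terminated_early: bool = False
    n_proposals: int = 0
    logged_steps: list[int] = field(default_factory=list)
    novel_sets: list[frozenset[bytes]] = field(default_factory=list)
    unique_fractions: list[float] = field(default_factory=list)
    final: Genotype | None = None

    @property
    def n_accepted(self) -> int:
        return len(self.steps)


def neighborhood_phenotypes(genotype: Genotype, universe: ReactionUniverse,
                            demand) -> NeighborhoodResult:
    """Evaluate all single-reaction toggles of a genotype.

    Returns the distinct phenotype vectors (encoded as bytes) of demand-viable
    neighbors whose phenotype differs from the focal one, plus classification
    counts.  Phenotypes are compared as full vectors over every candidate
    source.
    """
    model = get_model(universe)
    demand = as_demand(demand)
    focal_key = phenotype_key(model.phenotype(genotype))
    novel: set[bytes] = set()
    n_inviable = n_same = n_novel = 0
    for idx in range(universe.size):
        neighbor = genotype.with_bit(idx, not genotype.bits[idx])
        if not model.meets_demand(neighbor, demand):
            n_inviable += 1
            continue
        key = phenotype_key(model.phenotype(neighbor))
        if key == focal_key:
            n_same += 1
        else:
            n_novel += 1
            novel.add(key)
    return NeighborhoodResult(novel=frozenset(novel), n_inviable=n_inviable,
                              n_same=n_same, n_novel=n_novel)


def unique_fraction(novel_gk: Iterable[bytes], novel_g: Iterable[bytes]) -> float:
    """|novel(G_k) \\ novel(G)| / |novel(G_k)|, or 0 if novel(G_k) is empty."""
    gk = set(novel_gk)
    if not gk:
        return 0.0
    return len(gk - set(novel_g)) / len(gk)


def cumulative_novel(walk_or_sets) -> np.ndarray:
    """Running count of distinct novel phenotypes over logged steps.

    Accepts a :class:`WalkRecord` (uses its logged neighborhood sets) or any
    iterable of phenotype-key sets.  The result is non-decreasing.
    """
    sets = (walk_or_sets.novel_sets if isinstance(walk_or_sets, WalkRecord)
            else list(walk_or_sets))
    seen: set[bytes] = set()
    out = np.empty(len(sets), dtype=int)
    for i, s in enumerate(sets):
        seen.update(s)
        out[i] = len(seen)
    return out


def neutral_walk(start: Genotype, universe: ReactionUniverse, demand,
                 n_accepted: int, rng: np.random.Generator,
                 forced: bool = False,
                 log_neighborhoods_every: int | None = None) -> WalkRecord:
    """Run a phenotype-preserving random walk of ``n_accepted`` mutations.

    At size N an addition is proposed (a uniformly random absent reaction);
    at size N+1 a deletion (a uniformly random present reaction).  A proposal
    is accepted iff the mutant stays viable on the demand and, in forced
    mode, does not re-add a start reaction nor decrease the distance to the
    start.  Because the distance of a size-N and a size-N+1 state to the
    start are normalized differently, the forced non-decrease constraint
    compares each proposal against the last visited state of the *same*
    size, which makes the number of reactions shared with the start a pure
    ratchet.  Rejections leave the state (and the alternation turn)
    unchanged.  If no acceptable proposal exists the walk terminates early
    with the steps recorded so far.

    ``log_neighborhoods_every=k`` evaluates the full one-mutant neighborhood
    at the start and after every k-th accepted step, recording the novel
    phenotype sets and the fraction unique relative to the start's
    neighborhood.
    """
    demand = as_demand(demand)
    model = get_model(universe)
    if not model.meets_demand(start, demand):
        raise ValueError("walk start is not viable on the demand")
    if n_accepted < 0:
        raise ValueError("n_accepted must be >= 0")
    record = WalkRecord(start=start, demand=tuple(demand), forced=forced)
    n0 = start.size
    current = start
    # last distance seen at each network size (N and N+1), for forced mode
    last_dist = {n0: 0.0, n0 + 1: -np.inf}

    start_novel: frozenset[bytes] = frozenset()
    if log_neighborhoods_every:
        nb = neighborhood_phenotypes(start, universe, demand)
        start_novel = nb.novel
        record.logged_steps.append(0)
        record.novel_sets.append(nb.novel)
        record.unique_fractions.append(0.0)

    for step in range(1, n_accepted + 1):
        adding = current.size == n0
        if adding:
            candidates = np.flatnonzero(~current.bits)
            if forced:
                candidates = candidates[~start.bits[candidates]]
            op = "add"
        else:
            candidates = np.flatnonzero(current.bits)
            op = "del"
        new_size = current.size + (1 if adding else -1)
        accepted = None
        for idx in rng.permutation(candidates):
            record.n_proposals += 1
            mutant = current.with_bit(idx, adding)
            new_dist = distance(mutant, start)
            if forced and new_dist < last_dist[new_size] - 1e-12:
                continue
            if model.meets_demand(mutant, demand):
                accepted = (idx, mutant, new_dist)
                break
        if accepted is None:
            record.terminated_early = True
            break
        idx, current, cur_dist = accepted
        last_dist[new_size] = max(last_dist[new_size], cur_dist)
        record.steps.append((step, op, universe.reactions[idx].id))
        record.distances.append(cur_dist)
        if current.size == n0:
            record.d_max = max(record.d_max, cur_dist)
        if log_neighborhoods_every and step % log_neighborhoods_every == 0:
            nb = neighborhood_phenotypes(current, universe, demand)
            record.logged_steps.append(step)
            record.novel_sets.append(nb.novel)
            record.unique_fractions.append(unique_fraction(nb.novel, start_novel))
    record.final = current
    return record
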