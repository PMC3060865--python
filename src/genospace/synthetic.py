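"""Synthetic reaction universes with constructive ground truth.

The generator emits small reaction universes that emulate the statistical
structure the genotype-space analysis assumes, without any external data:

* a designated focal element ``"X"`` whose metabolites define candidate sole
  sources, and a filler element ``"C"`` so that elemental balance checks are
  exercised non-trivially;
* a biomass reaction consuming a small set of focal-element precursors;
* assimilation pathways from every source to a hub metabolite, either as
  independent linear chains or as a convergent tree in which nearby sources
  share downstream segments (the funnelled topology of real assimilatory
  metabolism);
* ``redundancy`` parallel alternative reactions per conversion step, so that
  minimal networks are non-unique, reactions can be substituted, and
  superessential sets are non-trivial;
* salvage reactions from each precursor back to the hub, so that *every*
  focal-element metabolite occurring in a reaction can act as a sole source;
* element-free decoy reactions that are never essential for any demand.

Because every pathway is built as an explicit series of *steps* (edges of a
step DAG) with a known list of alternative reactions per step, the complete
family of minimal demand-viable networks and the superessential set of any
demand are available **by construction** — no search — via :class:`GroundTruth`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .universe import Metabolite, Reaction, ReactionUniverse

__all__ = ["SyntheticSpec", "GroundTruth", "FixtureCase",
           "generate_universe", "make_fixture_suite"]

ELEMENT = "X"
FILLER = "FIL"


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic universe.

    n_sources:    number of leaf source metabolites of the focal element.
    n_precursors: number of focal-element biomass precursors (2-5 sensible).
    depth:        pathway length (steps) from a leaf source to the hub.
    redundancy:   parallel alternative reactions per conversion step (r >= 1);
                  with r = 1 the minimal network per demand is unique.
    n_decoys:     element-free reactions irrelevant to viability.
    trunk_steps:  number of final pre-hub steps forced to a single route,
                  giving demands a non-trivial superessential "trunk".
    route_steps:  reactions per alternative route (route-private
                  intermediates); with > 1, swapping a route requires
                  several additions before any deletion is possible, the
                  multi-reaction pathway substitution of real metabolism.
    precursor_route_steps: route length of the hub-to-precursor steps
                  (defaults to route_steps); single-step precursor routes
                  make reactions substitutable by one addition, driving the
                  decline of essential-reaction counts with network size.
    topology:     "linear" (independent chains per source) or "convergent"
                  (sources merge pairwise towards the hub).
    filler_stoich: filler molecules consumed per step (2 exercises non-unit
                  coefficients while keeping the reachability oracle valid).
    seed:         fixes the reaction-position shuffle.
    """

    n_sources: int = 3
    n_precursors: int = 2
    depth: int = 3
    redundancy: int = 1
    n_decoys: int = 2
    trunk_steps: int = 0
    route_steps: int = 1
    precursor_route_steps: int | None = None
    topology: str = "linear"
    filler_stoich: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.redundancy < 1:
            raise ValueError("redundancy must be >= 1")
        if self.n_sources < 1 or self.n_precursors < 1 or self.depth < 1:
            raise ValueError("n_sources, n_precursors and depth must be >= 1")
        if self.route_steps < 1:
            raise ValueError("route_steps must be >= 1")
        if self.topology not in ("linear", "convergent"):
            raise ValueError(f"unknown topology {self.topology!r}")


@dataclass
class GroundTruth:
    """Constructive ground truth for a synthetic universe.

    ``edges`` maps a step id to the list of interchangeable *routes*
    implementing that step, each route a tuple of reaction ids.
    ``path_edges`` maps every focal-element metabolite to the step ids
    leading from it to the hub (empty for the hub itself; the salvage step
    for a precursor; a route-tail pseudo-step for route-private
    intermediates).  A demand-viable minimal network is exactly one route
    choice per needed step.
    """

    edges: dict[str, list[tuple[str, ...]]]
    path_edges: dict[str, tuple[str, ...]]
    precursor_edges: dict[str, str]
    leaf_sources: list[str]
    hub: str
    decoy_reactions: list[str] = field(default_factory=list)
    tail_dst: dict[str, str] = field(default_factory=dict)

    def needed_edges(self, environment_source: str) -> tuple[str, ...]:
        """Steps required for viability with this metabolite as sole source.

        A precursor supplied by the environment — directly, or as the product
        of the source's own route tail — does not need its hub-side step.
        """
        path = self.path_edges[environment_source]
        supplied = {environment_source, self.tail_dst.get(environment_source)}
        prec = tuple(e for p, e in self.precursor_edges.items()
                     if p not in supplied)
        return path + prec

    def demand_edges(self, demand: list[str] | tuple[str, ...]) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for source in demand:
            for e in self.needed_edges(source):
                seen.setdefault(e)
        return tuple(seen)

    def n_min(self, demand) -> int:
        """Size of every minimal demand-viable network (routes have equal length)."""
        return sum(len(self.edges[e][0]) for e in self.demand_edges(demand))

    def n_minimal_sets(self, demand) -> int:
        n = 1
        for e in self.demand_edges(demand):
            n *= len(self.edges[e])
        return n

    def minimal_sets(self, demand, limit: int = 100_000) -> list[frozenset[str]]:
        """All minimal demand-viable reaction sets, by construction."""
        needed = self.demand_edges(demand)
        if self.n_minimal_sets(demand) > limit:
            raise ValueError(
                f"{self.n_minimal_sets(demand)} minimal sets exceed the "
                f"enumeration limit {limit}; use n_min/superessential instead")
        return [frozenset(r for route in choice for r in route)
                for choice in itertools.product(*(self.edges[e] for e in needed))]

    def superessential(self, demand) -> frozenset[str]:
        """Reactions present in every minimal demand-viable network."""
        return frozenset(r for e in self.demand_edges(demand)
                         if len(self.edges[e]) == 1
                         for r in self.edges[e][0])


def _formula(level: int, fs: int) -> dict[str, int]:
    f = {ELEMENT: 1}
    if level * fs:
        f["C"] = level * fs
    return f


def generate_universe(spec: SyntheticSpec) -> tuple[ReactionUniverse, GroundTruth]:
    """Build a synthetic universe and its constructive ground truth.

    Every reaction is elementally balanced by construction, and the full
    universe is viable on every candidate sole source.
    """
    fs = spec.filler_stoich
    metabolites: dict[str, Metabolite] = {
        FILLER: Metabolite(FILLER, {"C": 1})}

    levels: dict[str, int] = {}

    def add_met(mid: str, level: int) -> str:
        if mid not in metabolites:
            metabolites[mid] = Metabolite(mid, _formula(level, fs))
            levels[mid] = level
        return mid
    edges: dict[str, list[tuple[str, ...]]] = {}
    edge_order: list[str] = []
    reactions: list[Reaction] = []
    # route-private intermediate -> (remaining reactions of its route, edge dst)
    route_tails: dict[str, tuple[tuple[str, ...], str]] = {}
    q = spec.route_steps

    def add_step_reaction(rid: str, src: str, dst: str) -> None:
        stoich = {src: -1.0, dst: 1.0}
        if fs:
            stoich[FILLER] = stoich.get(FILLER, 0.0) - float(fs)
        reactions.append(Reaction(id=rid, stoichiometry=stoich))

    def add_edge(src: str, dst: str, n_routes: int, steps: int | None = None) -> str:
        eid = f"{src}>{dst}"
        src_level = levels.get(src, 0)
        nq = q if steps is None else steps
        routes = []
        for k in range(n_routes):
            tag = f"{eid}#{k}" if n_routes > 1 else eid
            rids = []
            prev = src
            for step in range(1, nq + 1):
                node = dst if step == nq else f"{tag}~{step}"
                if node != dst:
                    add_met(node, src_level + step)
                rid = tag if nq == 1 else f"{tag}.{step}"
                add_step_reaction(rid, prev, node)
                rids.append(rid)
                prev = node
            routes.append(tuple(rids))
            for i, rid in enumerate(rids[:-1]):
                node = f"{tag}~{i + 1}"
                route_tails[node] = (tuple(rids[i + 1:]), dst)
        edges[eid] = routes
        edge_order.append(eid)
        return eid

    leaf_sources = [f"SRC{i}" for i in range(spec.n_sources)]
    for s in leaf_sources:
        add_met(s, 0)
        levels[s] = 0
    # metabolite -> path of edge ids towards the hub, filled as we build
    parent_edge: dict[str, tuple[str, str]] = {}  # node -> (edge id, parent)

    if spec.topology == "linear":
        total_depth = spec.depth
        hub = "HUB"
        add_met(hub, total_depth * q)
        for i, s in enumerate(leaf_sources):
            prev = s
            for l in range(1, spec.depth + 1):
                node = hub if l == spec.depth else add_met(f"A{i}_{l}", l * q)
                trunk = l > spec.depth - spec.trunk_steps
                eid = add_edge(prev, node, 1 if trunk else spec.redundancy)
                parent_edge[prev] = (eid, node)
                prev = node
    else:  # convergent
        current = list(leaf_sources)
        level = 0
        while len(current) > 1:
            level += 1
            nxt: list[str] = []
            for j in range(0, len(current), 2):
                parent = add_met(f"M{level}_{j // 2}", level * q)
                for child in current[j:j + 2]:
                    eid = add_edge(child, parent, spec.redundancy)
                    parent_edge[child] = (eid, parent)
                nxt.append(parent)
            current = nxt
        root, tree_height = current[0], level
        extra = max(spec.depth - tree_height, 0)
        total_depth = tree_height + extra
        prev = root
        for t in range(1, extra + 1):
            node = add_met("HUB" if t == extra else f"T{t}", (tree_height + t) * q)
            trunk = t > extra - spec.trunk_steps
            eid = add_edge(prev, node, 1 if trunk else spec.redundancy)
            parent_edge[prev] = (eid, node)
            prev = node
        hub = prev

    pq = spec.precursor_route_steps if spec.precursor_route_steps is not None else q
    precursors = [f"PRE{j}" for j in range(spec.n_precursors)]
    precursor_edges: dict[str, str] = {}
    for p in precursors:
        add_met(p, total_depth * q + pq)
        precursor_edges[p] = add_edge(hub, p, spec.redundancy, steps=pq)
    # salvage: precursor -> hub (+ filler back), so precursors work as sources
    for p in precursors:
        eid = f"{p}>{hub}"
        stoich = {p: -1.0, hub: 1.0}
        if fs:
            stoich[FILLER] = float(fs * pq)
        reactions.append(Reaction(id=eid, stoichiometry=stoich))
        edges[eid] = [(eid,)]
        edge_order.append(eid)
        parent_edge[p] = (eid, hub)

    decoy_ids = []
    if spec.n_decoys:
        for k in range(spec.n_decoys + 1):
            metabolites.setdefault(f"DEC{k}", Metabolite(f"DEC{k}", {"C": k + 1}))
        for k in range(spec.n_decoys):
            rid = f"DEC{k}>DEC{k + 1}"
            reactions.append(Reaction(
                id=rid, reversible=True,
                stoichiometry={f"DEC{k}": -1.0, FILLER: -1.0, f"DEC{k + 1}": 1.0}))
            decoy_ids.append(rid)

    biomass_formula: dict[str, int] = {}
    for p in precursors:
        for el, n in metabolites[p].formula.items():
            biomass_formula[el] = biomass_formula.get(el, 0) + n
    metabolites["BIOMASS"] = Metabolite("BIOMASS", biomass_formula)
    biomass = Reaction(id="BIOMASS_RXN",
                       stoichiometry={**{p: -1.0 for p in precursors},
                                      "BIOMASS": 1.0})

    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(len(reactions))
    reactions = [reactions[i] for i in order]

    universe = ReactionUniverse(reactions=reactions, metabolites=metabolites,
                                element=ELEMENT, biomass=biomass)

    # paths from every focal-element metabolite to the hub; route-private
    # intermediates get a single-route pseudo-step for their route tail
    path_edges: dict[str, tuple[str, ...]] = {}
    tail_dst: dict[str, str] = {}
    for mid, met in metabolites.items():
        if not met.contains(ELEMENT) or mid == "BIOMASS":
            continue
        path: list[str] = []
        node = mid
        if node in route_tails:
            tail, dst = route_tails[node]
            tail_eid = f"tail:{node}"
            edges[tail_eid] = [tail]
            path.append(tail_eid)
            tail_dst[mid] = dst
            node = dst
        while node != hub:
            eid, node = parent_edge[node]
            path.append(eid)
        path_edges[mid] = tuple(path)

    truth = GroundTruth(edges=edges, path_edges=path_edges,
                        precursor_edges=precursor_edges,
                        leaf_sources=leaf_sources, hub=hub,
                        decoy_reactions=decoy_ids, tail_dst=tail_dst)
    return universe, truth


@dataclass
class FixtureCase:
    """A canonical toy case with its expected ground truth."""

    name: str
    spec: SyntheticSpec
    universe: ReactionUniverse
    truth: GroundTruth
    demand: tuple[str, ...]

    @property
    def expected_n_min(self) -> int:
        return self.truth.n_min(self.demand)

    @property
    def expected_minimal_sets(self) -> set[frozenset[str]]:
        return set(self.truth.minimal_sets(self.demand))

    @property
    def expected_superessential(self) -> frozenset[str]:
        return self.truth.superessential(self.demand)


def make_fixture_suite(out_dir=None) -> list[FixtureCase]:
    """The canonical toy cases shared across module tests.

    unique:       r = 1, a single minimal network per demand.
    parallel:     two fully disjoint routes everywhere; superessential set
                  empty in the many-replicate limit.
    shared_trunk: redundant steps feeding a unique pre-hub trunk reaction.
    decoy_rich:   padded with element-free reactions that are never essential.

    If ``out_dir`` is given, each universe is serialized in the canonical TSV
    dialect alongside a JSON ground-truth summary.
    """
    specs = {
        "unique": SyntheticSpec(n_sources=2, n_precursors=1, depth=2,
                                redundancy=1, n_decoys=1, seed=11),
        "parallel": SyntheticSpec(n_sources=1, n_precursors=1, depth=2,
                                  redundancy=2, n_decoys=0, seed=12),
        "shared_trunk": SyntheticSpec(n_sources=2, n_precursors=2, depth=3,
                                      redundancy=2, trunk_steps=1, n_decoys=1,
                                      seed=13),
        "decoy_rich": SyntheticSpec(n_sources=2, n_precursors=1, depth=2,
                                    redundancy=2, n_decoys=6, seed=14),
    }
    cases = []
    for name, spec in specs.items():
        universe, truth = generate_universe(spec)
        cases.append(FixtureCase(name=name, spec=spec, universe=universe,
                                 truth=truth,
                                 demand=(truth.leaf_sources[0],)))
    if out_dir is not None:
        import json
        from pathlib import Path
        from .universe import write_universe

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for case in cases:
            write_universe(case.universe, out / f"{case.name}.tsv")
            summary = {
                "demand": list(case.demand),
                "n_min": case.expected_n_min,
                "minimal_sets": sorted(sorted(s) for s in case.expected_minimal_sets),
                "superessential": sorted(case.expected_superessential),
            }
            (out / f"{case.name}.truth.json").write_text(
                json.dumps(summary, indent=1) + "\n")
    return cases
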