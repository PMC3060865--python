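"""Graph-reachability viability check for unit-stoichiometry universes.

For universes without cofactor coupling and with (near-)unit stoichiometry,
steady-state FBA viability coincides with a much simpler criterion: starting
from the sole source plus every non-focal-element metabolite, iteratively fire
every present reaction whose substrates are all available (either direction
for reversibles) until a fixed point, and ask whether every focal-element
biomass precursor becomes producible.  This "metabolite scope" closure is an
independent algorithm from the LP path and serves as its cross-check oracle
on synthetic universes.
"""

from __future__ import annotations

from .fba import Genotype
from .universe import ReactionUniverse

__all__ = ["reachable_metabolites", "viable_by_reachability"]


def reachable_metabolites(genotype: Genotype, universe: ReactionUniverse,
                          sole_source: str) -> set[str]:
    """The closure of producible metabolites in a sole-source environment."""
    available = {m for m, met in universe.metabolites.items()
                 if not met.contains(universe.element)}
    available.add(sole_source)
    # candidate firings: (frozenset substrates, products) per direction
    firings = []
    for i, rxn in enumerate(universe.reactions):
        if not genotype.bits[i]:
            continue
        firings.append((rxn.substrates, rxn.products))
        if rxn.reversible:
            firings.append((rxn.products, rxn.substrates))
    changed = True
    while changed:
        changed = False
        remaining = []
        for subs, prods in firings:
            if all(s in available for s in subs):
                new = [p for p in prods if p not in available]
                if new:
                    available.update(new)
                    changed = True
            else:
                remaining.append((subs, prods))
        firings = remaining
    return available


def viable_by_reachability(genotype: Genotype, universe: ReactionUniverse,
                           sole_source: str) -> bool:
    """True iff every biomass substrate is producible from the sole source."""
    if universe.biomass is None:
        raise ValueError("universe has no biomass reaction")
    scope = reachable_metabolites(genotype, universe, sole_source)
    return all(m in scope for m in universe.biomass.substrates)
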