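"""Shared fixtures: canonical toy universes with constructive ground truth."""

from __future__ import annotations

import numpy as np
import pytest

from genospace.fba import Genotype
from genospace.reachability import viable_by_reachability
from genospace.synthetic import make_fixture_suite


@pytest.fixture(scope="session")
def fixture_suite():
    return {case.name: case for case in make_fixture_suite()}


@pytest.fixture(scope="session")
def unique_case(fixture_suite):
    """r = 1: a single minimal network per demand."""
    return fixture_suite["unique"]


@pytest.fixture(scope="session")
def parallel_case(fixture_suite):
    """Fully disjoint parallel routes; empty superessential set."""
    return fixture_suite["parallel"]


@pytest.fixture(scope="session")
def shared_trunk_case(fixture_suite):
    """Redundant steps feeding a unique pre-hub trunk reaction."""
    return fixture_suite["shared_trunk"]


@pytest.fixture(scope="session")
def decoy_case(fixture_suite):
    """Padded with element-free reactions that are never essential."""
    return fixture_suite["decoy_rich"]


def enumerate_minimal_sets(universe, demand) -> set[frozenset[str]]:
    """Brute-force enumeration of minimal demand-viable reaction sets.

    Uses the graph-reachability oracle (valid on the unit-stoichiometry
    synthetic universes), independent of both the LP path and the generator's
    constructive ground truth.  Exponential in the universe size.
    """
    n = universe.size
    if n > 17:
        raise ValueError(f"U={n} too large for exhaustive enumeration")
    viable = np.zeros(2 ** n, dtype=bool)
    for mask in range(2 ** n):
        bits = np.array([(mask >> i) & 1 for i in range(n)], dtype=bool)
        genotype = Genotype(bits, universe.key)
        viable[mask] = all(viable_by_reachability(genotype, universe, s)
                           for s in demand)
    minimal = set()
    for mask in np.flatnonzero(viable):
        mask = int(mask)
        if all(not viable[mask & ~(1 << i)]
               for i in range(n) if (mask >> i) & 1):
            minimal.add(frozenset(universe.reactions[i].id
                                  for i in range(n) if (mask >> i) & 1))
    return minimal
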