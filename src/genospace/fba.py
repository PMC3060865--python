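"""Viability phenotyping by flux balance analysis (FBA).

A genotype (a presence/absence vector over the universe's reactions) is
*viable* in an environment whose sole focal-element source is metabolite *s*
if the linear program

    maximize  v_biomass
    s.t.      S v = 0            (steady state: one mass balance per metabolite)
              0 <= v_r           (every present reaction; reversibles split)
              0 <= u_m <= b      (uptake of every allowed metabolite)
              0 <= e_m           (secretion of every metabolite, unbounded)

attains an optimum strictly greater than the viability threshold
(1.0e-3 flux units).  The environment is rich in everything except the focal
element: every metabolite that does not contain the focal element may be taken
up, plus the single designated source.  The *phenotype* of a genotype is the
binary vector, over all candidate sources, of these viability verdicts.

The LP is solved with scipy's HiGHS backend over a sparse stoichiometric
matrix assembled once per universe; per-call work is limited to adjusting
variable bounds, which makes the heavy neighbor-enumeration loops of the
walk and population modules affordable.  Verdicts are memoized per
(universe, genotype, source) — semantically transparent caching that the
random-walk modules rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linprog

from .universe import ReactionUniverse

__all__ = [
    "VIABILITY_THRESHOLD",
    "Environment",
    "Genotype",
    "FbaResult",
    "FluxBalanceModel",
    "get_model",
    "build_lp",
    "is_viable",
    "phenotype_of",
    "meets_demand",
    "phenotype_key",
]

#: A genotype is viable iff its maximal biomass rate exceeds this (strictly).
VIABILITY_THRESHOLD = 1.0e-3

#: Guard band against LP round-off when comparing against the threshold: an
#: optimum within 1e-9 of the threshold is treated as exactly at it (inviable).
_THRESHOLD_GUARD = 1e-9


@dataclass(frozen=True)
class Environment:
    """A sole-source environment: rich in everything but the focal element."""

    sole_source: str
    uptake_bound: float = 10.0


@dataclass
class FbaResult:
    biomass_rate: float
    status: str  # "optimal" | "infeasible" | "unbounded"
    viable: bool


class Genotype:
    """A metabolic network: a binary vector over the universe's reactions.

    Instances are immutable; mutation helpers return new genotypes.  ``key``
    is a compact hashable encoding used for phenotype caching and equality.
    """

    __slots__ = ("bits", "universe_key", "_key")

    def __init__(self, bits: np.ndarray, universe_key: str):
        bits = np.array(bits, dtype=bool)  # own copy; frozen below
        bits.setflags(write=False)
        self.bits = bits
        self.universe_key = universe_key
        self._key: bytes | None = None

    @classmethod
    def full(cls, universe: ReactionUniverse) -> "Genotype":
        return cls(np.ones(universe.size, dtype=bool), universe.key)

    @classmethod
    def empty(cls, universe: ReactionUniverse) -> "Genotype":
        return cls(np.zeros(universe.size, dtype=bool), universe.key)

    @classmethod
    def from_ids(cls, universe: ReactionUniverse,
                 reaction_ids: Iterable[str]) -> "Genotype":
        bits = np.zeros(universe.size, dtype=bool)
        for rid in reaction_ids:
            bits[universe.index_of(rid)] = True
        return cls(bits, universe.key)

    @property
    def size(self) -> int:
        """N: the number of reactions present."""
        return int(self.bits.sum())

    @property
    def key(self) -> bytes:
        if self._key is None:
            self._key = np.packbits(self.bits).tobytes()
        return self._key

    def with_bit(self, index: int, value: bool) -> "Genotype":
        bits = self.bits.copy()
        bits[index] = value
        return Genotype(bits, self.universe_key)

    def ids(self, universe: ReactionUniverse) -> list[str]:
        return [universe.reactions[i].id for i in np.flatnonzero(self.bits)]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Genotype):
            return NotImplemented
        return self.universe_key == other.universe_key and self.key == other.key

    def __hash__(self) -> int:
        return hash((self.universe_key, self.key))

    def __repr__(self) -> str:
        return f"Genotype(N={self.size}, U={self.bits.size})"


def phenotype_key(phenotype: np.ndarray) -> bytes:
    """Compact hashable encoding of a phenotype bit vector."""
    return np.packbits(np.asarray(phenotype, dtype=bool)).tobytes()


class FluxBalanceModel:
    """Reusable LP scaffold for one universe.

    Columns, in order: one or two (if reversible) flux columns per universe
    reaction, the biomass flux, one uptake column per metabolite, and one
    secretion column per metabolite.  Absent reactions and disallowed uptakes
    are expressed by clamping the corresponding bounds to zero, so the sparse
    equality matrix is built exactly once.
    """

    def __init__(self, universe: ReactionUniverse, uptake_bound: float = 10.0):
        if universe.biomass is None:
            raise ValueError("universe has no biomass reaction; FBA undefined")
        self.universe = universe
        self.uptake_bound = uptake_bound
        mets = list(universe.metabolites)
        self._met_index = {m: i for i, m in enumerate(mets)}
        n_mets = len(mets)

        rows: list[int] = []
        cols: list[int] = []
        vals: list[float] = []
        col = 0
        # reaction flux columns (forward, and backward for reversibles)
        self._rxn_cols: list[np.ndarray] = []
        for rxn in universe.reactions:
            own = [col]
            for met_id, coeff in rxn.stoichiometry.items():
                rows.append(self._met_index[met_id])
                cols.append(col)
                vals.append(coeff)
            col += 1
            if rxn.reversible:
                own.append(col)
                for met_id, coeff in rxn.stoichiometry.items():
                    rows.append(self._met_index[met_id])
                    cols.append(col)
                    vals.append(-coeff)
                col += 1
            self._rxn_cols.append(np.array(own))
        # biomass column
        self._bio_col = col
        for met_id, coeff in universe.biomass.stoichiometry.items():
            idx = self._met_index.get(met_id)
            if idx is None:
                raise ValueError(
                    f"biomass metabolite {met_id!r} missing from universe")
            rows.append(idx)
            cols.append(col)
            vals.append(coeff)
        col += 1
        # uptake (+1) and secretion (-1) columns per metabolite
        self._uptake_col0 = col
        for i in range(n_mets):
            rows.append(i)
            cols.append(col + i)
            vals.append(1.0)
        col += n_mets
        for i in range(n_mets):
            rows.append(i)
            cols.append(col + i)
            vals.append(-1.0)
        col += n_mets
        self.n_cols = col
        self._A = sp.csc_matrix(
            (vals, (rows, cols)), shape=(n_mets, self.n_cols))
        self._c = np.zeros(self.n_cols)
        self._c[self._bio_col] = -1.0

        # column index sets reused per call
        self._all_rxn_cols = np.concatenate(self._rxn_cols) if universe.size else np.array([], dtype=int)
        # base upper bounds: secretion unbounded, fluxes unbounded, uptake set per env
        self._base_ub = np.full(self.n_cols, np.inf)
        non_element = np.array(
            [not universe.metabolites[m].contains(universe.element) for m in mets])
        self._uptake_allowed_base = non_element
        self._cache: dict[tuple[bytes, str], bool] = {}
        self.n_lp_calls = 0

    # -- LP assembly and solving -------------------------------------------

    def _bounds(self, genotype: Genotype, environment: Environment) -> np.ndarray:
        ub = self._base_ub.copy()
        absent = ~genotype.bits
        if absent.any():
            off = np.concatenate([self._rxn_cols[i] for i in np.flatnonzero(absent)])
            ub[off] = 0.0
        n_mets = len(self._met_index)
        allowed = self._uptake_allowed_base.copy()
        src_idx = self._met_index.get(environment.sole_source)
        if src_idx is None:
            raise KeyError(f"unknown sole source {environment.sole_source!r}")
        allowed[src_idx] = True
        up = np.where(allowed, environment.uptake_bound, 0.0)
        ub[self._uptake_col0:self._uptake_col0 + n_mets] = up
        return ub

    def build_lp(self, genotype: Genotype, environment: Environment
                 ) -> tuple[np.ndarray, sp.csc_matrix, np.ndarray]:
        """Return (c, A_eq, upper_bounds) of the viability LP (lower bounds 0)."""
        self._check(genotype)
        return self._c, self._A, self._bounds(genotype, environment)

    def _check(self, genotype: Genotype) -> None:
        if genotype.universe_key != self.universe.key:
            raise ValueError("genotype does not belong to this universe")

    def solve(self, genotype: Genotype, environment: Environment) -> FbaResult:
        c, A, ub = self.build_lp(genotype, environment)
        bounds = np.column_stack([np.zeros(self.n_cols), ub])
        self.n_lp_calls += 1
        res = linprog(c, A_eq=A, b_eq=np.zeros(A.shape[0]), bounds=bounds,
                      method="highs")
        if res.status == 0:
            rate = max(0.0, -res.fun)
            return FbaResult(rate, "optimal",
                             rate > VIABILITY_THRESHOLD + _THRESHOLD_GUARD)
        if res.status == 3:
            return FbaResult(float("inf"), "unbounded", True)
        if res.status == 2:
            return FbaResult(0.0, "infeasible", False)
        # numerical trouble: retry once with a tightened feasibility tolerance
        res = linprog(c, A_eq=A, b_eq=np.zeros(A.shape[0]), bounds=bounds,
                      method="highs",
                      options={"primal_feasibility_tolerance": 1e-10,
                               "dual_feasibility_tolerance": 1e-10})
        if res.status == 0:
            rate = max(0.0, -res.fun)
            return FbaResult(rate, "optimal",
                             rate > VIABILITY_THRESHOLD + _THRESHOLD_GUARD)
        raise RuntimeError(
            f"LP solver failed (status {res.status}) for source "
            f"{environment.sole_source!r}")

    # -- cached qualitative calls ------------------------------------------

    def viable_on(self, genotype: Genotype, source: str) -> bool:
        """Cached viability verdict for one sole-source environment."""
        self._check(genotype)
        key = (genotype.key, source)
        hit = self._cache.get(key)
        if hit is None:
            hit = self.solve(
                genotype, Environment(source, self.uptake_bound)).viable
            self._cache[key] = hit
        return hit

    def phenotype(self, genotype: Genotype) -> np.ndarray:
        """Viability over every candidate sole source, as a bool vector."""
        return np.array([self.viable_on(genotype, s)
                         for s in self.universe.sources])

    def meets_demand(self, genotype: Genotype, demand: Sequence[str]) -> bool:
        return all(self.viable_on(genotype, s) for s in demand)


def get_model(universe: ReactionUniverse,
              uptake_bound: float = 10.0) -> FluxBalanceModel:
    """Memoized FluxBalanceModel for a universe (shared phenotype cache)."""
    cached = getattr(universe, "_fba_model", None)
    if cached is None or cached.uptake_bound != uptake_bound:
        cached = FluxBalanceModel(universe, uptake_bound)
        universe._fba_model = cached
    return cached


# ---------------------------------------------------------------------------
# Thin functional surface
# ---------------------------------------------------------------------------

def build_lp(genotype: Genotype, universe: ReactionUniverse,
             environment: Environment):
    return get_model(universe, environment.uptake_bound).build_lp(
        genotype, environment)


def is_viable(genotype: Genotype, universe: ReactionUniverse,
              environment: Environment) -> FbaResult:
    return get_model(universe, environment.uptake_bound).solve(
        genotype, environment)


def phenotype_of(genotype: Genotype, universe: ReactionUniverse) -> np.ndarray:
    return get_model(universe).phenotype(genotype)


def meets_demand(phenotype: np.ndarray, demand_indices: Sequence[int]) -> bool:
    """True iff the demanded source bits are a subset of the phenotype bits."""
    phenotype = np.asarray(phenotype, dtype=bool)
    return all(phenotype[i] for i in demand_indices)
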