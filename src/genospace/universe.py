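"""Reaction universes: the fixed alphabet of metabolic genotype space.

A *reaction universe* is an ordered set of candidate biochemical reactions over
a pool of metabolites with known elemental formulas.  A metabolic genotype is a
presence/absence vector over this ordered set, so the universe fixes both the
dimensionality of genotype space and the meaning of every position.  One
chemical element (sulfur, ``"S"``, in the real-data path) is singled out as the
*focal* element: the metabolites that contain it and occur in at least one
universe reaction are the candidate sole sources defining environments, and a
distinguished biomass reaction consumes the focal-element biomass precursors.

The module builds universes from KEGG LIGAND-style flat files merged with an
SBML constraint-based model, or from the synthetic generator
(:mod:`genospace.synthetic`), applying the pruning filters that make a raw
reaction list suitable for stoichiometric analysis: generic polymer reactions,
glycan chemistry, elementally unbalanced reactions, and metabolites without
structural information are removed.
"""

from __future__ import annotations

import json
import re
import uuid
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Metabolite",
    "Reaction",
    "ReactionUniverse",
    "UniverseError",
    "parse_formula",
    "format_formula",
    "check_balance",
    "prune_universe",
    "enumerate_sources",
    "read_universe",
    "write_universe",
    "read_kegg_reactions",
    "read_kegg_compounds",
    "merge_sbml_model",
]


class UniverseError(ValueError):
    """Raised for malformed or inconsistent universe inputs."""


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")
_POLYMER_MARK = re.compile(r"\)n|\(.*\)\s*n|n[+-]?\d*\s*$")


def parse_formula(text: str) -> dict[str, int] | None:
    """Parse an elemental formula string like ``"C2H6OS"`` into counts.

    Returns ``None`` for polymer-style or otherwise unparseable formulas
    (e.g. ``"(C2H4)n"``), which marks the metabolite as structureless.
    """
    text = text.strip()
    if not text or _POLYMER_MARK.search(text) or "n" in text or "*" in text:
        return None
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(text):
        if match.start() != pos:
            return None
        pos = match.end()
        element, num = match.groups()
        counts[element] = counts.get(element, 0) + (int(num) if num else 1)
    if pos != len(text):
        return None
    return counts


def format_formula(formula: Mapping[str, int]) -> str:
    """Render a formula map as a Hill-ordered string (C, H, then alphabetical)."""
    def key(el: str) -> tuple[int, str]:
        return ({"C": 0, "H": 1}.get(el, 2), el)

    parts = []
    for el in sorted(formula, key=key):
        n = formula[el]
        if n:
            parts.append(el + (str(n) if n != 1 else ""))
    return "".join(parts)


@dataclass
class Metabolite:
    """A chemical compound with an elemental composition.

    ``formula`` is ``None`` when no structural information is available
    (such metabolites are pruned together with their reactions).
    """

    id: str
    formula: dict[str, int] | None = None
    polymer: bool = False
    glycan: bool = False

    def count(self, element: str) -> int:
        if self.formula is None:
            return 0
        return self.formula.get(element, 0)

    def contains(self, element: str) -> bool:
        return self.count(element) > 0

    @property
    def contains_sulfur(self) -> bool:
        return self.contains("S")


@dataclass
class Reaction:
    """A stoichiometric reaction.

    ``stoichiometry`` maps metabolite id to a signed coefficient: negative for
    substrates, positive for products.  Reversible reactions are stored once;
    the FBA layer splits them into two irreversible fluxes.
    """

    id: str
    stoichiometry: dict[str, float]
    reversible: bool = False
    polymer: bool = False
    glycan: bool = False

    @property
    def substrates(self) -> list[str]:
        return [m for m, c in self.stoichiometry.items() if c < 0]

    @property
    def products(self) -> list[str]:
        return [m for m, c in self.stoichiometry.items() if c > 0]


def check_balance(reaction: Reaction, metabolites: Mapping[str, Metabolite],
                  tol: float = 1e-9) -> bool:
    """True iff every element's atom count balances between the two sides.

    Raises :class:`UniverseError` if a referenced metabolite is unknown or has
    no formula.
    """
    totals: dict[str, float] = {}
    for met_id, coeff in reaction.stoichiometry.items():
        met = metabolites.get(met_id)
        if met is None:
            raise UniverseError(
                f"reaction {reaction.id!r} references unknown metabolite {met_id!r}")
        if met.formula is None:
            raise UniverseError(
                f"reaction {reaction.id!r} references metabolite {met_id!r} "
                "without a formula")
        for element, n in met.formula.items():
            totals[element] = totals.get(element, 0.0) + coeff * n
    return all(abs(v) <= tol for v in totals.values())


@dataclass
class ReactionUniverse:
    """The global candidate-reaction set over which genotypes are defined.

    ``reactions`` order is significant: it fixes genotype-vector positions and
    is preserved across serialization round trips.  ``sources`` lists, in
    stable order, every focal-element metabolite occurring in at least one
    reaction: the candidate sole sources.  ``biomass`` is the distinguished
    growth reaction; it is always present in every network and is never a
    member of ``reactions``.
    """

    reactions: list[Reaction]
    metabolites: dict[str, Metabolite]
    element: str = "S"
    biomass: Reaction | None = None
    sources: list[str] = field(default_factory=list)
    key: str = field(default_factory=lambda: uuid.uuid4().hex, compare=False)

    def __post_init__(self) -> None:
        if not self.sources:
            self.sources = enumerate_sources(self)
        self._index = {r.id: i for i, r in enumerate(self.reactions)}
        if len(self._index) != len(self.reactions):
            raise UniverseError("duplicate reaction id in universe")
        self._source_index = {s: i for i, s in enumerate(self.sources)}

    @property
    def size(self) -> int:
        """U: the number of candidate reactions (genotype-vector length)."""
        return len(self.reactions)

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def index_of(self, reaction_id: str) -> int:
        return self._index[reaction_id]

    def source_index(self, metabolite_id: str) -> int:
        return self._source_index[metabolite_id]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReactionUniverse):
            return NotImplemented
        return (self.element == other.element
                and self.reactions == other.reactions
                and self.metabolites == other.metabolites
                and self.biomass == other.biomass
                and self.sources == other.sources)


def enumerate_sources(universe: ReactionUniverse) -> list[str]:
    """All focal-element metabolites participating in >= 1 universe reaction.

    Order is stable: first appearance over reactions in universe order, then
    within a reaction in stoichiometry insertion order.
    """
    seen: dict[str, None] = {}
    for reaction in universe.reactions:
        for met_id in reaction.stoichiometry:
            if met_id in seen:
                continue
            met = universe.metabolites.get(met_id)
            if met is not None and met.contains(universe.element):
                seen[met_id] = None
    return list(seen)


def prune_universe(raw_reactions: Iterable[Reaction],
                   metabolites: Mapping[str, Metabolite],
                   biomass: Reaction | None = None,
                   element: str = "S") -> ReactionUniverse:
    """Filter a raw reaction list down to a stoichiometrically sound universe.

    Applies, in one pass and preserving input order, the four filters that
    make reaction data usable for flux balance analysis:

    (i)   reactions involving generic polymer metabolites (``A_n + B -> A_n+1``
          style chemistry, flagged or with unparseable formulas),
    (ii)  reactions involving glycans,
    (iii) reactions that are not stoichiometrically/elementally balanced,
    (v)   reactions involving metabolites without structural information.

    (The filter numbering skips (iv) deliberately; the upstream enumeration
    it mirrors has no fourth item.)  Pruning is idempotent.
    """
    survivors: list[Reaction] = []
    kept_mets: dict[str, Metabolite] = {}
    for reaction in raw_reactions:
        mets = []
        ok = not (reaction.polymer or reaction.glycan)
        if ok:
            for met_id in reaction.stoichiometry:
                met = metabolites.get(met_id)
                if met is None or met.formula is None or met.polymer or met.glycan:
                    ok = False
                    break
                mets.append(met)
        if ok and not reaction.substrates:
            ok = False
        if ok and not reaction.products:
            ok = False
        if ok and not check_balance(reaction, metabolites):
            ok = False
        if ok:
            survivors.append(reaction)
            for met in mets:
                kept_mets[met.id] = met
    if not survivors:
        raise UniverseError("empty universe: no reaction survived pruning")
    if biomass is not None:
        for met_id in biomass.stoichiometry:
            met = metabolites.get(met_id)
            if met is not None:
                kept_mets.setdefault(met_id, met)
    return ReactionUniverse(reactions=survivors, metabolites=kept_mets,
                            element=element, biomass=biomass)


# ---------------------------------------------------------------------------
# Canonical TSV / JSON serialization
# ---------------------------------------------------------------------------

def _format_stoichiometry(stoich: Mapping[str, float]) -> str:
    parts = []
    for met_id, coeff in stoich.items():
        sign = "+" if coeff > 0 else "-"
        mag = abs(coeff)
        mag_str = f"{mag:g}"
        parts.append(f"{sign}{mag_str} {met_id}")
    return " ".join(parts)


def _parse_stoichiometry(text: str, reaction_id: str) -> dict[str, float]:
    tokens = text.split()
    if len(tokens) % 2 != 0:
        raise UniverseError(f"malformed stoichiometry for {reaction_id!r}: {text!r}")
    stoich: dict[str, float] = {}
    for i in range(0, len(tokens), 2):
        coeff_str, met_id = tokens[i], tokens[i + 1]
        try:
            coeff = float(coeff_str)
        except ValueError as exc:
            raise UniverseError(
                f"malformed coefficient {coeff_str!r} in reaction {reaction_id!r}") from exc
        if coeff == 0:
            raise UniverseError(f"zero coefficient in reaction {reaction_id!r}")
        if met_id in stoich:
            raise UniverseError(
                f"metabolite {met_id!r} repeated in reaction {reaction_id!r}")
        stoich[met_id] = coeff
    return stoich


def _metabolites_path(path: Path) -> Path:
    return path.with_name(path.stem + ".metabolites.tsv")


def write_universe(universe: ReactionUniverse, path: str | Path,
                   format: str = "tsv") -> None:
    """Serialize a universe to the canonical TSV pair or a single JSON file.

    The TSV dialect writes ``<path>`` (reactions: reaction_id, reversible,
    role, stoichiometry) and ``<stem>.metabolites.tsv`` (id, formula, flags).
    ``read_universe`` o ``write_universe`` is the identity, including reaction
    order.
    """
    path = Path(path)
    if format == "json":
        payload = {
            "element": universe.element,
            "metabolites": [
                {"id": m.id,
                 "formula": format_formula(m.formula) if m.formula else "",
                 "polymer": m.polymer, "glycan": m.glycan}
                for m in universe.metabolites.values()
            ],
            "reactions": [
                {"id": r.id, "reversible": r.reversible,
                 "stoichiometry": _format_stoichiometry(r.stoichiometry)}
                for r in universe.reactions
            ],
            "biomass": (
                {"id": universe.biomass.id,
                 "stoichiometry": _format_stoichiometry(universe.biomass.stoichiometry)}
                if universe.biomass else None),
        }
        path.write_text(json.dumps(payload, indent=1) + "\n")
        return
    if format != "tsv":
        raise UniverseError(f"unknown universe format {format!r}")
    lines = [f"# element\t{universe.element}",
             "reaction_id\treversible\trole\tstoichiometry"]
    for r in universe.reactions:
        lines.append(f"{r.id}\t{int(r.reversible)}\treaction\t"
                     f"{_format_stoichiometry(r.stoichiometry)}")
    if universe.biomass is not None:
        b = universe.biomass
        lines.append(f"{b.id}\t0\tbiomass\t{_format_stoichiometry(b.stoichiometry)}")
    path.write_text("\n".join(lines) + "\n")
    met_lines = ["id\tformula\tpolymer\tglycan"]
    for m in universe.metabolites.values():
        formula = format_formula(m.formula) if m.formula else ""
        met_lines.append(f"{m.id}\t{formula}\t{int(m.polymer)}\t{int(m.glycan)}")
    _metabolites_path(path).write_text("\n".join(met_lines) + "\n")


def _reaction_from_record(rid: str, reversible: bool, stoich_text: str,
                          seen: set[str]) -> Reaction:
    if rid in seen:
        raise UniverseError(f"duplicate reaction id {rid!r}")
    seen.add(rid)
    return Reaction(id=rid, reversible=reversible,
                    stoichiometry=_parse_stoichiometry(stoich_text, rid))


def read_universe(path: str | Path, format: str = "tsv") -> ReactionUniverse:
    """Read a universe from the canonical TSV pair or JSON file."""
    path = Path(path)
    if format == "json":
        payload = json.loads(path.read_text())
        metabolites = {
            m["id"]: Metabolite(id=m["id"],
                                formula=parse_formula(m["formula"]) if m["formula"] else None,
                                polymer=bool(m.get("polymer")),
                                glycan=bool(m.get("glycan")))
            for m in payload["metabolites"]
        }
        seen: set[str] = set()
        reactions = [
            _reaction_from_record(r["id"], bool(r["reversible"]), r["stoichiometry"], seen)
            for r in payload["reactions"]
        ]
        biomass = None
        if payload.get("biomass"):
            b = payload["biomass"]
            biomass = Reaction(id=b["id"],
                               stoichiometry=_parse_stoichiometry(b["stoichiometry"], b["id"]))
        return ReactionUniverse(reactions=reactions, metabolites=metabolites,
                                element=payload["element"], biomass=biomass)
    if format != "tsv":
        raise UniverseError(f"unknown universe format {format!r}")
    element = "S"
    reactions: list[Reaction] = []
    biomass: Reaction | None = None
    seen = set()
    for line in path.read_text().splitlines():
        if line.startswith("# element\t"):
            element = line.split("\t", 1)[1].strip()
            continue
        if not line or line.startswith("#") or line.startswith("reaction_id\t"):
            continue
        fields = line.split("\t")
        if len(fields) != 4:
            raise UniverseError(f"malformed universe row: {line!r}")
        rid, rev, role, stoich_text = fields
        if role == "biomass":
            if biomass is not None:
                raise UniverseError("multiple biomass rows")
            biomass = Reaction(id=rid,
                               stoichiometry=_parse_stoichiometry(stoich_text, rid))
        else:
            reactions.append(_reaction_from_record(rid, rev == "1", stoich_text, seen))
    metabolites: dict[str, Metabolite] = {}
    for line in _metabolites_path(path).read_text().splitlines():
        if not line or line.startswith("id\t"):
            continue
        mid, formula, polymer, glycan = line.split("\t")
        if mid in metabolites:
            raise UniverseError(f"duplicate metabolite id {mid!r}")
        metabolites[mid] = Metabolite(
            id=mid, formula=parse_formula(formula) if formula else None,
            polymer=polymer == "1", glycan=glycan == "1")
    return ReactionUniverse(reactions=reactions, metabolites=metabolites,
                            element=element, biomass=biomass)


# ---------------------------------------------------------------------------
# KEGG LIGAND flat files and SBML model merging
# ---------------------------------------------------------------------------

def _split_kegg_records(text: str) -> list[dict[str, str]]:
    records = []
    for chunk in text.split("///"):
        if not chunk.strip():
            continue
        fields: dict[str, str] = {}
        key = None
        for line in chunk.splitlines():
            if not line.strip():
                continue
            head = line[:12].strip()
            if head:
                key = head
                fields[key] = line[12:].strip()
            elif key:
                fields[key] += " " + line[12:].strip()
        records.append(fields)
    return records


_TERM = re.compile(r"^\s*(?:(\d+|n(?:[+-]\d+)?)\s+)?([A-Z]\d{5}|[A-Za-z]\w*)\s*$")


def read_kegg_reactions(path: str | Path) -> list[Reaction]:
    """Parse a KEGG LIGAND REACTION flat file into raw reactions.

    Handles ENTRY/EQUATION records; polymerization equations with symbolic
    ``n`` coefficients and glycan (``G#####``) participants are kept but
    flagged so that pruning can discard them.
    """
    reactions = []
    for record in _split_kegg_records(Path(path).read_text()):
        entry = record.get("ENTRY", "").split()
        equation = record.get("EQUATION")
        if not entry or not equation:
            continue
        rid = entry[0]
        reversible = "<=>" in equation
        sep = "<=>" if reversible else "=>"
        lhs, _, rhs = equation.partition(sep)
        stoich: dict[str, float] = {}
        polymer = glycan = False
        for side, sign in ((lhs, -1.0), (rhs, 1.0)):
            for term in side.split(" + "):
                match = _TERM.match(term)
                if not match:
                    polymer = True
                    continue
                coeff_str, met_id = match.groups()
                if coeff_str and not coeff_str.isdigit():
                    polymer = True
                    coeff = 1.0
                else:
                    coeff = float(coeff_str) if coeff_str else 1.0
                if met_id.startswith("G") and met_id[1:].isdigit():
                    glycan = True
                stoich[met_id] = stoich.get(met_id, 0.0) + sign * coeff
        stoich = {m: c for m, c in stoich.items() if c != 0}
        reactions.append(Reaction(id=rid, stoichiometry=stoich,
                                  reversible=reversible,
                                  polymer=polymer, glycan=glycan))
    return reactions


def read_kegg_compounds(path: str | Path) -> dict[str, Metabolite]:
    """Parse a KEGG LIGAND COMPOUND flat file into metabolites."""
    from Bio.KEGG import Compound

    metabolites: dict[str, Metabolite] = {}
    with open(path) as handle:
        for record in Compound.parse(handle):
            formula = parse_formula(record.formula) if record.formula else None
            metabolites[record.entry] = Metabolite(
                id=record.entry, formula=formula,
                polymer=bool(record.formula) and formula is None)
    return metabolites


def merge_sbml_model(reactions: list[Reaction],
                     metabolites: dict[str, Metabolite],
                     sbml_path: str | Path,
                     element: str = "S") -> tuple[list[Reaction], dict[str, Metabolite]]:
    """Merge reactions from an SBML constraint-based model into a raw set.

    Only model reactions involving at least one focal-element metabolite are
    added (exchange/sink pseudo-reactions are skipped); metabolite formulas
    are taken from the model.  Returns new (reactions, metabolites) with the
    model's contributions appended after the existing entries.
    """
    import cobra.io

    model = cobra.io.read_sbml_model(str(sbml_path))
    out_reactions = list(reactions)
    out_mets = dict(metabolites)
    existing = {r.id for r in out_reactions}
    for rxn in model.reactions:
        if rxn.boundary:
            continue
        formulas = {}
        for met, coeff in rxn.metabolites.items():
            formulas[met.id] = parse_formula(met.formula or "")
        if not any(f and f.get(element, 0) > 0 for f in formulas.values()):
            continue
        if rxn.id in existing:
            continue
        for met in rxn.metabolites:
            out_mets.setdefault(met.id, Metabolite(id=met.id, formula=formulas[met.id]))
        out_reactions.append(Reaction(
            id=rxn.id,
            stoichiometry={m.id: float(c) for m, c in rxn.metabolites.items()},
            reversible=rxn.lower_bound < 0))
        existing.add(rxn.id)
    return out_reactions, out_mets
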