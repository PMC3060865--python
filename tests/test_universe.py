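"""Universe construction, pruning, serialization and format readers."""

import textwrap

import pytest

from genospace.universe import (Metabolite, Reaction, ReactionUniverse,
                                UniverseError, check_balance,
                                enumerate_sources, format_formula,
                                merge_sbml_model, parse_formula,
                                prune_universe, read_kegg_compounds,
                                read_kegg_reactions, read_universe,
                                write_universe)


def met(mid, formula, **kw):
    return Metabolite(mid, parse_formula(formula), **kw)


@pytest.mark.parametrize("formula,expected", [
    ("CH4S", {"C": 1, "H": 4, "S": 1}),
    ("C6H12O6", {"C": 6, "H": 12, "O": 6}),
    ("H2O", {"H": 2, "O": 1}),
    ("Fe2S2", {"Fe": 2, "S": 2}),
    ("(C2H4)n", None),          # polymer: no fixed composition
    ("C2H6(CH2)n", None),
    ("", None),
])
def test_parse_formula(formula, expected):
    assert parse_formula(formula) == expected


def test_format_formula_hill_order():
    assert format_formula({"S": 1, "H": 4, "C": 1}) == "CH4S"


class TestCheckBalance:
    mets = {
        "A": met("A", "CH4S"), "B": met("B", "CH4S"), "C": met("C", "CH4"),
        "H2": met("H2", "H2"), "O2": met("O2", "O2"), "H2O": met("H2O", "H2O"),
    }

    def test_identical_formulas_balance(self):
        rxn = Reaction("r", {"A": -1.0, "B": 1.0})
        assert check_balance(rxn, self.mets)

    def test_textbook_water_balance(self):
        rxn = Reaction("r", {"H2": -2.0, "O2": -1.0, "H2O": 2.0})
        assert check_balance(rxn, self.mets)

    def test_lost_sulfur_atom_fails(self):
        rxn = Reaction("r", {"A": -1.0, "C": 1.0})
        assert not check_balance(rxn, self.mets)

    def test_unknown_metabolite_diagnostic(self):
        rxn = Reaction("rx", {"A": -1.0, "ZZ": 1.0})
        with pytest.raises(UniverseError, match="rx.*ZZ"):
            check_balance(rxn, self.mets)


class TestPrune:
    mets = {
        "A": met("A", "CH4S"), "B": met("B", "CH4S"), "C": met("C", "CH4"),
        "POL": Metabolite("POL", None, polymer=True),
        "GLY": met("GLY", "C6H12O6", glycan=True),
        "NOF": Metabolite("NOF", None),
    }

    def test_unbalanced_and_flagged_reactions_removed(self):
        raw = [
            Reaction("ok", {"A": -1.0, "B": 1.0}),
            Reaction("unbalanced", {"A": -1.0, "C": 1.0}),
            Reaction("poly", {"POL": -1.0, "A": -1.0, "B": 1.0}),
            Reaction("glycan_rxn", {"GLY": -1.0, "A": -1.0, "B": 1.0, "C": 1.0}),
            Reaction("noformula", {"NOF": -1.0, "B": 1.0}),
            Reaction("ok2", {"B": -1.0, "A": 1.0}),
        ]
        universe = prune_universe(raw, self.mets)
        assert universe.reaction_ids == ["ok", "ok2"]

    def test_polymerization_form_removed(self):
        # A_n + B -> A_n+1 style growth: polymer metabolite has no formula
        raw = [Reaction("grow", {"POL": -1.0, "A": -1.0, "POL2": 1.0}),
               Reaction("ok", {"A": -1.0, "B": 1.0})]
        mets = dict(self.mets, POL2=Metabolite("POL2", None, polymer=True))
        assert prune_universe(raw, mets).reaction_ids == ["ok"]

    def test_pruning_is_idempotent(self):
        raw = [Reaction("ok", {"A": -1.0, "B": 1.0}),
               Reaction("bad", {"A": -1.0, "C": 1.0})]
        once = prune_universe(raw, self.mets)
        twice = prune_universe(once.reactions, once.metabolites)
        assert once == twice

    def test_empty_survivor_set_is_an_error(self):
        raw = [Reaction("bad", {"A": -1.0, "C": 1.0})]
        with pytest.raises(UniverseError, match="empty universe"):
            prune_universe(raw, self.mets)

    def test_pruned_universe_is_fully_balanced(self, fixture_suite):
        for case in fixture_suite.values():
            u = case.universe
            assert all(check_balance(r, u.metabolites) for r in u.reactions)


class TestSources:
    def test_counts_element_metabolites_in_reactions(self):
        mets = {f"M{i}": met(f"M{i}", "CH4S" if i < 3 else "CH4")
                for i in range(10)}
        raw = [Reaction(f"r{i}", {f"M{i}": -1.0, f"M{(i + 5) % 10}": 1.0})
               for i in range(3)]
        # only balanced reactions survive; M0..M2 are the S carriers
        universe = ReactionUniverse(
            reactions=raw, metabolites=mets, element="S")
        assert sorted(universe.sources) == ["M0", "M1", "M2"]

    def test_no_element_metabolite_gives_empty_list(self):
        mets = {"A": met("A", "CH4"), "B": met("B", "CH4")}
        universe = ReactionUniverse(
            reactions=[Reaction("r", {"A": -1.0, "B": 1.0})],
            metabolites=mets, element="S")
        assert enumerate_sources(universe) == []

    def test_sources_invariant_under_round_trip(self, tmp_path, fixture_suite):
        for case in fixture_suite.values():
            path = tmp_path / f"{case.name}.tsv"
            write_universe(case.universe, path)
            assert read_universe(path).sources == case.universe.sources


class TestSerialization:
    @pytest.mark.parametrize("fmt", ["tsv", "json"])
    def test_round_trip_is_identity(self, tmp_path, fixture_suite, fmt):
        for case in fixture_suite.values():
            ext = "tsv" if fmt == "tsv" else "json"
            path = tmp_path / f"{case.name}.{ext}"
            write_universe(case.universe, path, format=fmt)
            back = read_universe(path, format=fmt)
            assert back == case.universe
            # second write is bit-exact (order preserved)
            path2 = tmp_path / f"{case.name}2.{ext}"
            write_universe(back, path2, format=fmt)
            assert path2.read_text() == path.read_text()

    def test_duplicate_reaction_id_rejected(self, tmp_path):
        path = tmp_path / "u.tsv"
        path.write_text("# element\tS\n"
                        "reaction_id\treversible\trole\tstoichiometry\n"
                        "r1\t0\treaction\t-1 A +1 B\n"
                        "r1\t0\treaction\t-1 B +1 A\n")
        (tmp_path / "u.metabolites.tsv").write_text(
            "id\tformula\tpolymer\tglycan\nA\tCH4S\t0\t0\nB\tCH4S\t0\t0\n")
        with pytest.raises(UniverseError, match="duplicate"):
            read_universe(path)

    def test_malformed_stoichiometry_rejected(self, tmp_path):
        path = tmp_path / "u.tsv"
        path.write_text("# element\tS\n"
                        "reaction_id\treversible\trole\tstoichiometry\n"
                        "r1\t0\treaction\t-1 A +1\n")
        (tmp_path / "u.metabolites.tsv").write_text(
            "id\tformula\tpolymer\tglycan\nA\tCH4S\t0\t0\n")
        with pytest.raises(UniverseError, match="malformed"):
            read_universe(path)


KEGG_REACTIONS = textwrap.dedent("""\
    ENTRY       R00001                      Reaction
    EQUATION    C00001 + C00002 <=> 2 C00003
    ///
    ENTRY       R00002                      Reaction
    EQUATION    C00003 => C00004
    ///
    ENTRY       R00003                      Reaction
    EQUATION    C00005(n) + C00002 => C00005(n+1)
    ///
    ENTRY       R00004                      Reaction
    EQUATION    G00001 + C00001 => C00002 + G00002
    ///
""")

KEGG_COMPOUNDS = textwrap.dedent("""\
    ENTRY       C00001                      Compound
    NAME        Thing one
    FORMULA     H2S
    ///
    ENTRY       C00002                      Compound
    FORMULA     H2S
    ///
    ENTRY       C00003                      Compound
    FORMULA     H2S
    ///
    ENTRY       C00004                      Compound
    FORMULA     H2S
    ///
    ENTRY       C00005                      Compound
    FORMULA     (C2H4)n
    ///
""")


class TestKeggFlatFiles:
    def test_reaction_parsing_and_flags(self, tmp_path):
        path = tmp_path / "reaction"
        path.write_text(KEGG_REACTIONS)
        rxns = {r.id: r for r in read_kegg_reactions(path)}
        assert rxns["R00001"].reversible
        assert rxns["R00001"].stoichiometry == {
            "C00001": -1.0, "C00002": -1.0, "C00003": 2.0}
        assert not rxns["R00002"].reversible
        assert rxns["R00003"].polymer
        assert rxns["R00004"].glycan

    def test_compound_parsing_marks_polymers(self, tmp_path):
        path = tmp_path / "compound"
        path.write_text(KEGG_COMPOUNDS)
        mets = read_kegg_compounds(path)
        assert mets["C00001"].formula == {"H": 2, "S": 1}
        assert mets["C00005"].formula is None and mets["C00005"].polymer

    def test_flat_files_to_pruned_universe(self, tmp_path):
        (tmp_path / "reaction").write_text(KEGG_REACTIONS)
        (tmp_path / "compound").write_text(KEGG_COMPOUNDS)
        universe = prune_universe(
            read_kegg_reactions(tmp_path / "reaction"),
            read_kegg_compounds(tmp_path / "compound"))
        # the polymerization and glycan reactions are pruned; the two
        # elementally balanced ones survive in input order
        assert universe.reaction_ids == ["R00001", "R00002"]
        assert universe.sources == ["C00001", "C00002", "C00003", "C00004"]


class TestSbmlMerge:
    def _write_model(self, path):
        import cobra

        model = cobra.Model("mini")
        s_in = cobra.Metabolite("cys", formula="C3H7NO2S", compartment="c")
        s_out = cobra.Metabolite("met", formula="C3H7NO2S", compartment="c")
        c1 = cobra.Metabolite("glc", formula="C6H12O6", compartment="c")
        c2 = cobra.Metabolite("pyr", formula="C6H12O6", compartment="c")
        r1 = cobra.Reaction("SULFUR_RXN", lower_bound=-1000, upper_bound=1000)
        r1.add_metabolites({s_in: -1, s_out: 1})
        r2 = cobra.Reaction("CARBON_RXN", lower_bound=0, upper_bound=1000)
        r2.add_metabolites({c1: -1, c2: 1})
        model.add_reactions([r1, r2])
        cobra.io.write_sbml_model(model, str(path))

    def test_only_element_reactions_merged(self, tmp_path):
        sbml = tmp_path / "mini.xml"
        self._write_model(sbml)
        base = [Reaction("r0", {"A": -1.0, "B": 1.0})]
        mets = {"A": met("A", "CH4S"), "B": met("B", "CH4S")}
        rxns, all_mets = merge_sbml_model(base, mets, sbml, element="S")
        ids = [r.id for r in rxns]
        assert ids == ["r0", "SULFUR_RXN"]
        assert all_mets["cys"].formula == {"C": 3, "H": 7, "N": 1, "O": 2, "S": 1}
        merged = next(r for r in rxns if r.id == "SULFUR_RXN")
        assert merged.reversible
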