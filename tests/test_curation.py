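"""Standardization, balancing, chemical filters, additive enthalpy."""

import pytest

from cgrgen.curation import (
    BondEnergyTable,
    balance_with_water,
    chemical_filters,
    curate_corpus,
    estimate_enthalpy,
    filter_frequent_rcs,
    standardize,
    validate_generated,
)
from cgrgen.errors import BalanceFailure, MissingBondEnergyError
from cgrgen.graphs import compose_cgr, heavy_atom_balance, hydrogen_disbalance
from cgrgen.smiles import parse_reaction_smiles, write_reaction_smiles


def rxn_of(line, validate=True):
    return parse_reaction_smiles(line, validate=validate)


class TestStandardize:
    def test_identical_sides_discarded_as_empty(self):
        out, reason = standardize(rxn_of("[C:1][O:2]>>[C:1][O:2]"))
        assert out is None
        assert reason == "empty"

    def test_kekule_benzene_becomes_aromatic(self):
        out, _ = standardize(rxn_of("C1=CC=CC=C1.[Br:9][Br:10]>>BrC1=CC=CC=C1.Br"))
        assert out is not None
        flags = [a.aromatic for m in out.reactants for a in m.atoms if a.element == "C"]
        assert all(flags) and len(flags) == 6

    def test_pentavalent_carbon_discarded(self):
        bad = rxn_of("CC(C)(C)(C)C>>CC", validate=False)
        out, reason = standardize(bad)
        assert out is None
        assert reason == "valence"

    def test_corpus_survives_curation(self, corpus_reactions):
        kept, report = curate_corpus(corpus_reactions[:50])
        assert len(kept) == 50
        assert report.tallies()["standardize"] == {"kept": 50}


class TestFrequentRCs:
    def test_top_k_larger_than_classes_is_identity(self, corpus_reactions):
        sub = corpus_reactions[:60]
        assert filter_frequent_rcs(sub, 100) == sub

    def test_top_k_zero_is_empty(self, corpus_reactions):
        assert filter_frequent_rcs(corpus_reactions[:20], 0) == []

    def test_majority_classes_survive(self, small_corpus, corpus_reactions):
        from collections import Counter

        kept = filter_frequent_rcs(corpus_reactions, 3)
        counts = Counter(m["rc_class"] for m in small_corpus.manifest)
        top3 = {c for c, _n in counts.most_common(3)}
        kept_lines = {write_reaction_smiles(r) for r in kept}
        for line, entry in zip(small_corpus.lines, small_corpus.manifest):
            rxn = parse_reaction_smiles(line)
            if entry["rc_class"] in top3:
                assert write_reaction_smiles(rxn) in kept_lines
            else:
                assert write_reaction_smiles(rxn) not in kept_lines


class TestValidateGenerated:
    def test_report_driven_screen(self):
        strings = [
            "Brc1ccccc1",  # valid molecule
            "B([->.]c1ccccc1)(O)O",  # valid CGR
            "C1CC(",  # syntax
            "CC(C)(C)(C)[.>-]C",  # valence on product side
        ]
        kept, report = validate_generated(strings)
        assert [i for i, _ in kept] == [0, 1]
        tallies = report.tallies()["validate"]
        assert tallies == {"kept": 2, "discarded(syntax)": 1, "discarded(valence)": 1}


class TestBalanceWithWater:
    def test_amide_for_halide_becomes_fully_balanced(self, amide_for_halide_reaction):
        assert hydrogen_disbalance(amide_for_halide_reaction) == 2
        balanced = balance_with_water(amide_for_halide_reaction)
        assert hydrogen_disbalance(balanced) == 0
        assert heavy_atom_balance(balanced) == {}
        # boron product is now boric-ester-like B(O)(O)O
        boron_mol = next(
            m for m in balanced.products if any(a.element == "B" for a in m.atoms)
        )
        assert sum(1 for a in boron_mol.atoms if a.element == "O") == 3

    def test_balanced_input_is_noop(self):
        rxn = rxn_of("[C:1][Br:2].[C:3][B:4]([O:5])[O:6]>>[C:1][C:3].[Br:2][B:4]([O:5])[O:6]")
        assert balance_with_water(rxn) is rxn

    def test_two_boron_plus_four_fails(self):
        # two independent +2 events cannot be fixed by the single-water rule
        line = (
            "[C:1][C:2](=[O:3])[N:4][C:5].[O:6][B:7]([O:8])[C:9]."
            "[C:11][C:12](=[O:13])[N:14][C:15].[O:16][B:17]([O:18])[C:19]"
            ">>[C:1][C:2](=[O:3])[C:9].[N:4][C:5].[O:6][B:7][O:8]."
            "[C:11][C:12](=[O:13])[C:19].[N:14][C:15].[O:16][B:17][O:18]"
        )
        with pytest.raises(BalanceFailure):
            balance_with_water(rxn_of(line))

    def test_non_boron_disbalance_fails(self):
        rxn = rxn_of("[C:1][O:2]>>[C:1].[O:2]")  # +2 but no boron
        with pytest.raises(BalanceFailure):
            balance_with_water(rxn)


class TestChemicalFilters:
    def test_alkyl_cc_cleavage_fails(self):
        cgr = compose_cgr(rxn_of("[C:1][C:2].[Br:3]>>[C:1].[C:2][Br:3]"))
        passed, reasons = chemical_filters(cgr)
        assert not passed
        assert "CC_cleavage" in reasons

    def test_fluoride_leaving_passes(self):
        cgr = compose_cgr(
            rxn_of("[O:1].[B:2][C:3].[C:4][F:5]>>[O:1][B:2].[C:3][C:4].[F:5]")
        )
        passed, reasons = chemical_filters(cgr)
        assert passed, reasons

    def test_carbon_leaving_group_fails(self):
        # coupling expelling methane: the leaving fragment attaches via carbon
        cgr = compose_cgr(
            rxn_of("[O:1].[B:2][C:3].[N:4][C:5]>>[O:1][B:2].[C:3][N:4].[C:5]")
        )
        passed, reasons = chemical_filters(cgr)
        assert not passed
        assert "carbon_leaving_group" in reasons

    def test_unstable_sulfinyl_product_fails(self):
        # product carries S(=O) with a capping hydrogen
        cgr = compose_cgr(
            rxn_of("[C:1][Br:2].[S:3]=[O:4]>>[Br:2].[C:1][S:3]=[O:4]")
        )
        passed, reasons = chemical_filters(cgr)
        assert not passed
        assert any(r.startswith("unstable_group") for r in reasons)


class TestEnthalpy:
    def test_identity_reaction_is_zero(self):
        est = estimate_enthalpy(rxn_of("[C:1][C:2]>>[C:1][C:2]"))
        assert est.delta_h == 0.0

    def test_hydrogen_chlorination_matches_hand_sum(self):
        rxn = rxn_of("[H:1][H:2].[Cl:3][Cl:4]>>[H:1][Cl:3].[H:2][Cl:4]")
        est = estimate_enthalpy(rxn)
        assert est.delta_h == pytest.approx(-183.0)
        assert est.exothermic

    def test_reverse_negates(self, corpus_reactions):
        table = BondEnergyTable.load()
        for rxn in corpus_reactions[:30]:
            fwd = estimate_enthalpy(rxn, table).delta_h
            rev = estimate_enthalpy(rxn.reversed(), table).delta_h
            assert rev == pytest.approx(-fwd)

    def test_spectator_decoration_invariance(self):
        plain = rxn_of("[C:1][Br:2].[C:3][B:4]([O:5])[O:6]>>[C:1][C:3].[Br:2][B:4]([O:5])[O:6]")
        decorated = rxn_of(
            "[C:10][C:1][Br:2].[C:3]([C:11])[B:4]([O:5])[O:6]"
            ">>[C:10][C:1][C:3][C:11].[Br:2][B:4]([O:5])[O:6]"
        )
        table = BondEnergyTable.load()
        assert estimate_enthalpy(plain, table).delta_h == pytest.approx(
            estimate_enthalpy(decorated, table).delta_h
        )

    def test_missing_entry_named(self):
        table = BondEnergyTable({("C", "C", "-"): 347.0})
        with pytest.raises(MissingBondEnergyError, match="C-N|N-C"):
            estimate_enthalpy(rxn_of("[C:1][N:2]>>[C:1].[N:2]"), table)
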