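"""Core graph model: CGR composition, valence accounting, balances."""

import pytest

from cgrgen.errors import MappingError, UnsupportedElementError, ValenceError
from cgrgen.graphs import (
    AtomState,
    MoleculeGraph,
    check_valence,
    compose_cgr,
    decompose_cgr,
    heavy_atom_balance,
    hydrogen_disbalance,
    implicit_hydrogens,
)
from cgrgen.smiles import parse_reaction_smiles, write_reaction_smiles


def mol(atoms, bonds=(), maps=None):
    m = MoleculeGraph()
    for k, el in enumerate(atoms):
        m.add_atom(AtomState(el), map_id=None if maps is None else maps[k])
    for i, j, o in bonds:
        m.add_bond(i, j, o)
    return m


class TestComposeDecompose:
    def test_generic_suzuki_has_three_dynamic_bonds(self):
        rxn = parse_reaction_smiles("[B:1][C:2].[C:3][Br:4]>>[B:1].[C:2][C:3].[Br:4]")
        cgr = compose_cgr(rxn)
        assert cgr.dynamic_bonds() == {
            (1, 2): ("-", None),
            (2, 3): (None, "-"),
            (3, 4): ("-", None),
        }

    def test_identity_reaction_has_no_dynamic_bonds(self):
        rxn = parse_reaction_smiles("[C:1][C:2][O:3]>>[C:1][C:2][O:3]")
        assert compose_cgr(rxn).is_static()

    def test_amide_for_halide_dynamic_bond_inventory(self, amide_for_halide_reaction):
        # hand enumeration on the two-sided edge list: the unbalanced form
        # changes 3 bonds; its water-balanced form adds the B-O formation
        cgr = compose_cgr(amide_for_halide_reaction)
        dyn = cgr.dynamic_bonds()
        kinds = sorted(
            tuple(sorted((cgr.atoms[i].element, cgr.atoms[j].element))) + (ro, po)
            for (i, j), (ro, po) in dyn.items()
        )
        assert kinds == [
            ("B", "C", "-", None),   # boron-aryl cleavage
            ("C", "C", None, "-"),   # new C-C coupling bond
            ("C", "N", "-", None),   # amide C-N cleavage
        ]
        from cgrgen.curation import balance_with_water

        balanced = compose_cgr(balance_with_water(amide_for_halide_reaction))
        assert len(balanced.dynamic_bonds()) == 4  # adds B-O formation

    def test_duplicate_map_id_raises(self):
        with pytest.raises(MappingError):
            compose_cgr(parse_reaction_smiles("[C:1].[C:1]>>[C:1][C:2]", validate=False))

    def test_disjoint_maps_raise(self):
        with pytest.raises(MappingError):
            compose_cgr(parse_reaction_smiles("[C:1][C:2]>>[C:3][C:4]"))

    def test_decompose_of_static_cgr_gives_identical_sides(self):
        rxn = parse_reaction_smiles("[C:1][O:2]>>[C:1][O:2]")
        back = decompose_cgr(compose_cgr(rxn))
        assert write_reaction_smiles(back) == write_reaction_smiles(rxn)

    def test_suzuki_roundtrip_fragment_counts(self):
        rxn = parse_reaction_smiles("[B:1][C:2].[C:3][Br:4]>>[B:1].[C:2][C:3].[Br:4]")
        back = decompose_cgr(compose_cgr(rxn))
        assert len(back.reactants) == 2
        assert len(back.products) == 3

    def test_roundtrip_on_corpus(self, corpus_reactions):
        """decompose(compose(r)) reproduces r's mapped graphs (up to order)."""
        for rxn in corpus_reactions:
            back = decompose_cgr(compose_cgr(rxn))
            assert _canonical_sides(back) == _canonical_sides(rxn)

    def test_heavy_atoms_conserved_for_two_sided_cgrs(self, corpus_cgrs):
        for cgr in corpus_cgrs:
            if all(
                a.reactant_state is not None and a.product_state is not None
                for a in cgr.atoms.values()
            ):
                assert heavy_atom_balance(decompose_cgr(cgr)) == {}


def _canonical_sides(rxn):
    from cgrgen.smiles import write_molecule

    return (
        sorted(write_molecule(m, canonical=True) for m in rxn.reactants),
        sorted(write_molecule(m, canonical=True) for m in rxn.products),
    )


class TestValence:
    def test_methane_like_carbon_valid(self):
        m = mol("CHHHH"[:1])  # lone C: 4 implicit H
        assert check_valence(m) == []
        assert implicit_hydrogens(m) == [4]

    def test_pentavalent_carbon_reported(self):
        m = mol("CCCCCC", [(0, k, "-") for k in range(1, 6)])
        violations = check_valence(m)
        assert len(violations) == 1
        assert violations[0].element == "C"
        assert violations[0].observed == 5

    def test_neutral_trivalent_boron_valid(self):
        m = mol("BOOC", [(0, 1, "-"), (0, 2, "-"), (0, 3, "-")])
        assert check_valence(m) == []
        assert implicit_hydrogens(m)[0] == 0

    def test_unsupported_element(self):
        with pytest.raises(UnsupportedElementError):
            check_valence(mol(["Xx"]))

    @pytest.mark.parametrize(
        "atoms,bonds,expected",
        [
            (["O"], [], [2]),  # water
            (["O", "B"], [(0, 1, "-")], [1, 2]),  # decoded OB fragment
            (["C", "N"], [(0, 1, "-")], [3, 2]),  # decoded CN fragment
        ],
    )
    def test_implicit_hydrogens(self, atoms, bonds, expected):
        assert implicit_hydrogens(mol(atoms, bonds)) == expected

    def test_valence_error_propagates(self):
        m = mol("CCCCCC", [(0, k, "-") for k in range(1, 6)])
        with pytest.raises(ValenceError):
            implicit_hydrogens(m)


class TestBalances:
    def test_amide_for_halide_disbalance_is_plus_two(self, amide_for_halide_reaction):
        assert hydrogen_disbalance(amide_for_halide_reaction) == 2

    def test_balanced_methyl_suzuki_is_zero(self):
        # R-X + R'-B(OH)2 -> R-R' + X-B(OH)2 with R=CH3, X=Br, R'=CH3
        rxn = parse_reaction_smiles(
            "[C:1][Br:2].[C:3][B:4]([O:5])[O:6]"
            ">>[C:1][C:3].[Br:2][B:4]([O:5])[O:6]"
        )
        assert hydrogen_disbalance(rxn) == 0

    def test_reverse_negates_disbalance(self, amide_for_halide_reaction, corpus_reactions):
        assert hydrogen_disbalance(amide_for_halide_reaction.reversed()) == -2
        for rxn in corpus_reactions[:50]:
            assert hydrogen_disbalance(rxn.reversed()) == -hydrogen_disbalance(rxn)

    def test_heavy_atom_balance_water_coupling(self):
        rxn = parse_reaction_smiles("O.BC.N >  > OB.CN")
        assert heavy_atom_balance(rxn) == {}

    def test_heavy_atom_balance_detects_lost_amine(self):
        rxn = parse_reaction_smiles("O.BC.CN >  > OB.CC")
        assert heavy_atom_balance(rxn) == {"N": -1}

    def test_reaction_vs_itself_balanced(self, corpus_reactions):
        for rxn in corpus_reactions[:20]:
            same = type(rxn)(rxn.reactants, rxn.agents, rxn.reactants)
            assert heavy_atom_balance(same) == {}
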