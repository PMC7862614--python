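"""Reaction centers, environments, simplification, Suzuki matching."""

import random

import pytest

from cgrgen.center import (
    expand_environment,
    extract_rc,
    match_suzuki,
    simplify_cgr,
    simplify_reaction,
)
from cgrgen.errors import ArgumentError, NoReactionCenterError
from cgrgen.graphs import check_valence, compose_cgr
from cgrgen.novelty import signature
from cgrgen.smiles import parse_reaction_smiles, parse_smiles_cgr, write_smiles_cgr

SUZUKI = "[B:1][C:2].[C:3][Br:4]>>[B:1].[C:2][C:3].[Br:4]"


def cgr_of(line):
    return compose_cgr(parse_reaction_smiles(line, validate=False))


class TestExtract:
    def test_generic_suzuki_motif(self):
        (motif,) = extract_rc(cgr_of(SUZUKI))
        assert {motif.subgraph.atoms[i].element for i in motif.atom_ids} == {"B", "C"} | {"Br"}
        assert len(motif.subgraph.bonds) == 3

    def test_static_molecule_yields_no_motifs(self):
        assert extract_rc(parse_smiles_cgr("CCO")) == []

    def test_two_disjoint_events_give_two_motifs(self):
        line = (
            "[B:1][C:2].[C:3][Br:4].[B:5][C:6].[C:7][Cl:8]"
            ">>[B:1].[C:2][C:3].[Br:4].[B:5].[C:6][C:7].[Cl:8]"
        )
        motifs = extract_rc(cgr_of(line))
        assert len(motifs) == 2

    def test_commutes_with_renumbering(self, corpus_cgrs):
        rng = random.Random(5)
        for cgr in corpus_cgrs[:30]:
            ids = list(cgr.atoms)
            perm = ids[:]
            rng.shuffle(perm)
            renum = cgr.renumbered(dict(zip(ids, perm)))
            sigs = sorted(signature(m).hash for m in extract_rc(cgr))
            sigs2 = sorted(signature(m).hash for m in extract_rc(renum))
            assert sigs == sigs2


class TestExpand:
    def test_level_zero_is_identity(self, corpus_cgrs):
        cgr = corpus_cgrs[0]
        (motif,) = extract_rc(cgr)
        assert expand_environment(cgr, motif, 0).atom_ids == motif.atom_ids

    def test_phenyl_suzuki_first_shell(self):
        line = (
            "[O:1][B:2]([O:3])[c:4]1[cH:5][cH:6][cH:7][cH:8][cH:9]1.[Br:16][c:10]1[cH:11][cH:12][cH:13][cH:14][cH:15]1"
            ">>[Br:16][B:2]([O:1])[O:3].[c:4]1([cH:5][cH:6][cH:7][cH:8][cH:9]1)-[c:10]1[cH:11][cH:12][cH:13][cH:14][cH:15]1"
        )
        cgr = cgr_of(line)
        (motif,) = extract_rc(cgr)
        assert motif.atom_ids == {2, 4, 10, 16}
        rc1 = expand_environment(cgr, motif, 1)
        # adds boron's two oxygens and both ortho carbon pairs
        assert rc1.atom_ids == {2, 4, 10, 16, 1, 3, 5, 9, 11, 15}

    def test_monotone_and_closure(self, corpus_cgrs):
        for cgr in corpus_cgrs[:20]:
            for motif in extract_rc(cgr):
                sizes = [
                    len(expand_environment(cgr, motif, n).atom_ids) for n in range(6)
                ]
                assert sizes == sorted(sizes)
            # n >= diameter covers the whole connected part reachable
            big = expand_environment(cgr, extract_rc(cgr)[0], 50)
            comp_atoms = set()
            for comp in cgr.connected_components():
                if set(comp) & extract_rc(cgr)[0].atom_ids:
                    comp_atoms |= set(comp)
            assert big.atom_ids == comp_atoms

    def test_foreign_motif_rejected(self, corpus_cgrs):
        (motif,) = extract_rc(corpus_cgrs[0])
        other = parse_smiles_cgr("CCO")
        with pytest.raises(ArgumentError):
            expand_environment(other, motif, 1)


class TestSimplify:
    def test_decorated_reaction_loses_remote_substituents(self, amide_for_halide_reaction):
        cgr = compose_cgr(amide_for_halide_reaction)
        simple = simplify_reaction(cgr)
        elements = sorted(
            a.element for m in simple.reactants for a in m.atoms
        )
        # keeps carbonyl, benzylic CH2, B(OH)2 environment; methyl and both
        # rings survive only as far as the second shell allows
        assert "B" in elements and "N" in elements
        total_before = len(cgr.atoms)
        total_after = sum(len(m.atoms) for m in simple.reactants)
        assert total_after < total_before

    def test_minimal_pattern_is_fixed_point(self):
        cgr = cgr_of("[O:1].[B:2][C:3].[C:4][S:5]>>[O:1][B:2].[C:3][C:4].[S:5]")
        once = simplify_cgr(cgr)
        assert write_smiles_cgr(once) == write_smiles_cgr(cgr)

    def test_idempotent(self, corpus_cgrs):
        for cgr in corpus_cgrs[:30]:
            once = simplify_cgr(cgr)
            twice = simplify_cgr(once)
            assert write_smiles_cgr(twice) == write_smiles_cgr(once)

    def test_output_is_valence_valid(self, corpus_cgrs):
        for cgr in corpus_cgrs[:50]:
            simple = simplify_reaction(cgr)
            for mol in simple.reactants + simple.products:
                assert check_valence(mol) == []

    def test_no_rc_raises(self):
        with pytest.raises(NoReactionCenterError):
            simplify_cgr(parse_smiles_cgr("CCO"))


class TestMatchSuzuki:
    @pytest.mark.parametrize(
        "line,q,l",
        [
            ("[O:1].[B:2][C:3].[C:4][F:5]>>[O:1][B:2].[C:3][C:4].[F:5]", "C", "F"),
            ("[O:1].[B:2][C:3].[N:4]>>[O:1][B:2].[C:3][N:4]", "N", None),
            ("[O:1].[B:2][C:3].[C:4][S:5]>>[O:1][B:2].[C:3][C:4].[S:5]", "C", "S"),
        ],
    )
    def test_assignments(self, line, q, l):
        (motif,) = extract_rc(cgr_of(line))
        match = match_suzuki(motif)
        assert match is not None
        assert match.q_element == q
        assert match.l_element == l

    def test_boron_bromine_substitution_is_not_a_coupling(self):
        line = "[O:1].[B:2][C:3].[Br:4][N:5]>>[B:2][O:1].[C:3][Br:4].[N:5]"
        (motif,) = extract_rc(cgr_of(line))
        assert match_suzuki(motif) is None

    def test_ester_is_not_suzuki(self, corpus_cgrs, small_corpus):
        for cgr, entry in zip(corpus_cgrs, small_corpus.manifest):
            motifs = extract_rc(cgr)
            matched = any(match_suzuki(m) for m in motifs)
            if entry["class"] in ("ester", "amide"):
                assert not matched
            elif not entry["unbalanced"]:
                assert matched
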