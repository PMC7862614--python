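"""SMILES/CGR dialect: parsing, writing, canonicalization, tokenization."""

import random

import pytest

from cgrgen.errors import (
    EmptyReactionError,
    LengthError,
    SmilesSyntaxError,
    ValenceError,
    VocabularyError,
)
from cgrgen.graphs import decompose_cgr, heavy_atom_balance
from cgrgen.smiles import (
    parse_reaction_smiles,
    parse_smiles_cgr,
    write_reaction_smiles,
    write_smiles_cgr,
)
from cgrgen.tokenizer import (
    Vocabulary,
    detokenize,
    one_hot_decode,
    one_hot_encode,
    tokenize,
)


class TestParse:
    def test_broken_aryl_halide_bond(self):
        cgr = parse_smiles_cgr("Br[->.]c1ccccc1")
        ((_, orders),) = cgr.dynamic_bonds().items()
        assert orders == ("-", None)

    def test_static_string_is_plain_molecule(self):
        cgr = parse_smiles_cgr("CC")
        assert len(cgr.atoms) == 2
        assert cgr.is_static()

    def test_formed_bond_decomposes_to_methane_pair(self):
        cgr = parse_smiles_cgr("C[.>-]C")
        rxn = decompose_cgr(cgr)
        assert len(rxn.reactants) == 2
        assert len(rxn.products) == 1

    @pytest.mark.parametrize(
        "bad",
        ["C(", "C1CC", "[C", "C[->-]C", "C%1", "Cq", "[Zz]", "C[.>-]", "=C"],
    )
    def test_syntax_errors(self, bad):
        with pytest.raises(SmilesSyntaxError):
            parse_smiles_cgr(bad)

    def test_valence_error_on_either_side(self):
        # product side would give pentavalent carbon
        with pytest.raises(ValenceError):
            parse_smiles_cgr("CC(C)(C)(C)[.>-]C")

    def test_dynamic_charge_atom(self):
        cgr = parse_smiles_cgr("[N+>0](C)(C)C", validate=False)
        atom = next(a for a in cgr.atoms.values() if a.element == "N")
        assert atom.reactant_state.charge == 1
        assert atom.product_state.charge == 0
        assert atom.is_dynamic


class TestWrite:
    def test_write_parse_roundtrip_on_corpus(self, corpus_cgrs):
        for cgr in corpus_cgrs[:100]:
            s = write_smiles_cgr(cgr, canonical=True)
            again = write_smiles_cgr(parse_smiles_cgr(s, validate=False), canonical=True)
            assert again == s

    def test_canonical_invariance_under_renumbering(self):
        s = "CC(=O)N[->.]Cc1ccc(F)cc1.OB(O)c1ccc(OC)cc1"  # 30-atom CGR
        cgr = parse_smiles_cgr(s)
        canon = write_smiles_cgr(cgr)
        ids = list(cgr.atoms)
        rng = random.Random(42)
        for _ in range(1000):
            perm = ids[:]
            rng.shuffle(perm)
            renum = cgr.renumbered(dict(zip(ids, perm)))
            assert write_smiles_cgr(renum) == canon

    def test_canonicalization_is_fixed_point(self, corpus_strings):
        for s in corpus_strings[:100]:
            assert write_smiles_cgr(parse_smiles_cgr(s, validate=False)) == s


class TestReactionSmiles:
    def test_whitespace_tolerant_three_field_split(self):
        rxn = parse_reaction_smiles("O.BC.OI >  > OB.CO.I")
        assert len(rxn.reactants) == 3
        assert len(rxn.products) == 3

    def test_empty_reaction_raises(self):
        with pytest.raises(EmptyReactionError):
            parse_reaction_smiles(">>")

    def test_acyl_bromide_pattern_is_heavy_balanced(self):
        rxn = parse_reaction_smiles("BC.O.CBr >  > Br.CC.BO")
        assert heavy_atom_balance(rxn) == {}

    def test_roundtrip_with_maps(self, small_corpus):
        for line in small_corpus.lines[:20]:
            rxn = parse_reaction_smiles(line)
            again = parse_reaction_smiles(write_reaction_smiles(rxn))
            assert write_reaction_smiles(again) == write_reaction_smiles(rxn)


class TestTokenizer:
    @pytest.mark.parametrize(
        "s,expected",
        [
            ("C[.>-]Br", ["C", "[.>-]", "Br"]),
            ("", []),
            ("OB(O)c1ccccc1", list("OB(O)") + ["c", "1"] + ["c"] * 4 + ["c", "1"]),
        ],
    )
    def test_token_splits(self, s, expected):
        assert tokenize(s) == expected
        assert len(tokenize("OB(O)c1ccccc1")) == 13

    def test_inverse_law_on_corpus(self, corpus_strings):
        for s in corpus_strings:
            assert detokenize(tokenize(s)) == s

    def test_dangling_bracket(self):
        with pytest.raises(SmilesSyntaxError):
            tokenize("C[C")

    def test_one_hot_roundtrip(self, corpus_strings):
        vocab = Vocabulary.from_corpus(corpus_strings)
        for s in corpus_strings[:50]:
            toks = tokenize(s)
            mat = one_hot_encode(toks, vocab, max_len=80)
            assert mat.shape == (80, len(vocab))
            assert (mat.sum(axis=1) == 1).all()
            assert one_hot_decode(mat, vocab) == toks

    def test_one_hot_empty_is_all_pad(self):
        vocab = Vocabulary.from_corpus(["C"])
        mat = one_hot_encode([], vocab, max_len=4)
        assert (mat.argmax(axis=1) == vocab.index["<pad>"]).all()

    def test_one_hot_errors(self):
        vocab = Vocabulary.from_corpus(["C"])
        with pytest.raises(VocabularyError):
            one_hot_encode(["N"], vocab)
        with pytest.raises(LengthError):
            one_hot_encode(["C"] * 10, vocab, max_len=4)

    def test_vocabulary_json_roundtrip(self, tmp_path, corpus_strings):
        vocab = Vocabulary.from_corpus(corpus_strings)
        path = tmp_path / "vocab.json"
        vocab.save(path)
        again = Vocabulary.load(path)
        assert again.tokens == vocab.tokens
        assert again.index == vocab.index
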