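import numpy as np
import pytest

from cgrgen.graphs import compose_cgr
from cgrgen.smiles import parse_reaction_smiles, write_smiles_cgr
from cgrgen.synthetic import CorpusConfig, generate_corpus

# Generated-reaction pathology fixture: amide-for-halide Suzuki interpretation
# (acyl fragment as R with R=methyl, benzylamine leaving group, HB(OH)2 as
# the boron product), fully mapped.
AMIDE_FOR_HALIDE_LINE = (
    "[C:1][C:2](=[O:3])[N:4][C:5][c:6]1[cH:7][cH:8][cH:9][cH:10][cH:11]1."
    "[O:12][B:13]([O:14])[c:15]1[cH:16][cH:17][cH:18][cH:19][cH:20]1"
    ">>[C:1][C:2](=[O:3])-[c:15]1[cH:16][cH:17][cH:18][cH:19][cH:20]1."
    "[N:4][C:5][c:6]1[cH:7][cH:8][cH:9][cH:10][cH:11]1.[O:12][B:13][O:14]"
)


@pytest.fixture(scope="session")
def amide_for_halide_reaction():
    return parse_reaction_smiles(AMIDE_FOR_HALIDE_LINE)


@pytest.fixture(scope="session")
def small_corpus():
    """200-reaction default-condition corpus."""
    return generate_corpus(CorpusConfig(n_reactions=200, seed=7))


@pytest.fixture(scope="session")
def corpus_reactions(small_corpus):
    return [parse_reaction_smiles(l) for l in small_corpus.lines]


@pytest.fixture(scope="session")
def corpus_cgrs(corpus_reactions):
    return [compose_cgr(r) for r in corpus_reactions]


@pytest.fixture(scope="session")
def corpus_strings(corpus_cgrs):
    return [write_smiles_cgr(c) for c in corpus_cgrs]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
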