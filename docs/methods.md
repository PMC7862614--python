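# Methods

## The condensed-graph model

A mapped reaction `reactants > agents > products` is merged into one
**condensed graph of reaction**: atoms are keyed by their map number, and
every bond stores a pair *(reactant order, product order)* drawn from
`- = # :` plus "absent".  A bond whose two orders differ is *dynamic*; an
atom whose formal charge or radical state changes is a *dynamic atom*.  The
connected components of the dynamic subgraph are the reaction centers; a
CGR with several of them represents a multistep transformation.  Agents and
unmapped spectators never enter the CGR.

Atoms recorded on only one side of the source reaction (e.g. a leaving
group omitted from the product line) keep an *absent* state on the other
side.  Decomposition back to a reaction uses only the present sides, so
`decompose(compose(r))` reproduces the input reaction exactly — including
its imbalance.  Serialization is where information is deliberately lost:
the string dialect cannot mark absence, so the writer completes one-sided
fragments (attachment bond dynamic, internal bonds static).  Re-parsing
such a string yields the *balanced* interpretation in which the departed
fragment is a full product with hydrogen-capped valences — the origin of
the +2-hydrogen pathology that the water correction later repairs.  This
mirrors how sketchily recorded reactions corrupt sequence models trained on
them.

### Valence model

Implicit hydrogens are never stored; they are recomputed as the gap between
the observed explicit valence and the smallest allowed valence of the
element/charge/radical combination (table in `valence.py`: organic subset
plus B, Si, P, S, Se, halogens, and a few closed-shell metals).  Aromatic
bonds count 1.5 with half-down rounding so ring-fusion atoms (three
aromatic bonds, 4.5) resolve to valence 4.  A monoradical consumes one
valence unit.  These rules are the package's own, documented choice; they
reproduce all implicit-hydrogen counts the worked examples rely on.

### SMILES/CGR dialect and canonicalization

The grammar (full reference: `data/dialect.md`) is an OpenSMILES subset
plus dynamic bond tokens `[x>y]` and dynamic atom charge/radical changes
inside brackets.  One deliberate deviation: bracket atoms carry no explicit
hydrogen count — implicit hydrogens always come from the valence table —
which lets minimal patterns like `O.BC.N >> OB.CN` read as valid molecules.

Canonical output uses iterative neighborhood refinement (Morgan-style) over
an atom invariant that includes the per-side states and the multiset of
incident bond pairs; remaining ties are broken by recursively distinguishing
each tied atom and keeping the lexicographically smallest string.  Ties
that survive refinement are almost always automorphic in molecule-like
graphs, so the branching is cheap; a hard cap of 5000 explored leaves
bounds the worst case.  Canonicalization runs on the *written view*
(one-sided atoms completed), making every emitted string a parse/write
fixed point immediately.

## Reaction centers, environments, simplification

RC+n is the breadth-first n-shell closure of a center over bond hops, with
every bond among included atoms retained (level 0 keeps only the dynamic
bonds themselves).  *Simplified reactions* are the decomposition of the
sub-CGR induced on RC+2 — the "general reactivity pattern" with truncated
bonds capped by implicit hydrogens.  Aromatic systems cut by the boundary
are kept whole when at least half their atoms fall inside, otherwise the
included atoms are de-aromatized; this avoids emitting fragments of
aromatic rings that no valence model would accept.  Whether an RC+1 shell
should count atoms or bonds at ring fusions is ambiguous; the bond-hop BFS
is this package's documented choice.

## Novelty signatures

A motif's signature is the 64-bit blake2b digest of its canonical
SMILES/CGR string — deterministic across runs and platforms, isomorphism-
invariant by construction.  Tables store exemplar strings next to each
hash, so collisions are *detected* (lookup falls back to string equality)
rather than assumed absent.  Novelty levels: absent level-0 signature ⇒ new
reaction center; known center with absent level-1 signature ⇒ new first
environment; otherwise known.  For multistep CGRs the per-motif maximum is
reported (a repo choice; detail is preserved per motif).

## Autoencoder

Encoder: stacked bidirectional LSTM layers over one-hot token sequences
(bracket expressions and two-letter elements are single tokens); the
concatenated final hidden states of all layers and directions feed a tanh
bottleneck producing the latent vector.  Decoder: stacked forward LSTM
layers initialized from the latent through a dense layer, with the latent
also concatenated to the input at every step — generation from sampled
latents then does not depend on the initial state alone.  Training uses
teacher forcing, masked cross-entropy, Adam with gradient-norm clipping,
and a plateau schedule that halves the learning rate after `patience`
epochs without validation improvement.  Greedy argmax decoding is the
default and is deterministic; temperature sampling is available behind a
flag.  Defaults mirror the full-scale architecture (two 128-unit
bidirectional encoder layers, 128-d latent, two 256-unit decoder layers,
256-token padding, initial learning rate 0.005, batch 256, patience 2, 34
epochs).  Everything is implemented directly on numpy (float32 forward and
backward passes verified against numerical gradients), so training is
reproducible to floating-point accumulation order under a fixed seed and
thread count.

The desk-scale study in the test suite uses a reduced instance — 64-token
padding, 40-d latent, one 56-unit bidirectional encoder layer, one 128-unit
decoder layer, learning rate 0.004, batch 96, patience 3, 65 epochs — which
reaches ≥ 0.95 exact-string reconstruction on a held-out 10% of the default
2000-reaction corpus in a few minutes on one CPU.

## Generative topographic map

Standard GTM: a k×k node grid mapped through m×m Gaussian RBFs (width =
2× center spacing) and a linear weight matrix into latent space; the data
density is the equal-weight mixture of isotropic Gaussians at the node
images with shared precision β.  Initialization is PCA-based (grid aligned
to the first two principal axes; β from the larger of the third eigenvalue
and half the mean nearest-node-image distance).  The weight prior is a
fixed Gaussian (α = 10⁻³·β₀); holding α constant keeps the penalized
objective a single function that generalized EM increases monotonically —
the recorded per-iteration objective is asserted non-decreasing.  Defaults:
15×15 nodes, 7×7 RBFs (the desk-scale tests use 10×10 / 5×5).

Class landscapes are responsibility-weighted label fractions per node, with
summed responsibility as density; a *zone* is the node set exceeding purity
and density thresholds, and latent sampling draws uniformly over zone
nodes from N(node image, β⁻¹I).

## Curation and post-processing

Corpus curation: RDKit-backed aromatization and functional-group
normalization (nitro, azide, sulfoxide normal forms via the standardizer's
default transforms), removal of empty reactions (identical sides or a
missing side) and valence violations, and optional restriction to the
top-k most frequent level-0 signatures (deterministic tie-break by hash).

Decoded strings pass, in order: **validate** (parse + per-side valence) →
**balance** (the single-water correction, applicable exactly when the
hydrogen disbalance is +2 with heavy atoms balanced and a boron product
atom gained a capping hydrogen; anything else is discarded — no general
stoichiometry solver is attempted) → **simplify** → **novelty** →
**chemical filters** (C–C single-bond cleavage; leaving fragments — product
fragments containing no formed bond — attached through carbon; unstable
groups from a configurable SMARTS list seeded with S(=O)H and
H-phosphonate-ester motifs) → **enthalpy**.  Every decision is logged in a
CurationReport whose stage tallies are deterministic under fixed seeds.

The additive enthalpy uses a shipped mean-bond-enthalpy table
(Cottrell/CRC-style values, `data/bond_energies.tsv`).  Magnitudes are
table-dependent; within a reaction family only signs and orderings are
treated as meaningful, and implicit-hydrogen reorganization is not priced
(dynamic heavy-atom bonds only — spectator decoration provably cannot
change the estimate).

## Synthetic corpus

The generator emulates, at desk scale, a coupling-dominated reaction
extraction: 50% generalized Suzuki couplings (Q from a configurable pool,
leaving groups Br/Cl/I by default), 25% esterifications, 25% amide
couplings, decorated from a closed menu (methyl, methoxy, fluoro, nitro,
phenyl) that bounds string length; 10% of Suzuki entries omit the
boron-containing leaving species, reproducing the unbalanced-equation
pathology.  Reactions are built directly as CGRs and decomposed, so maps
and valences are correct by construction; a manifest records each
reaction's designed RC class and withheld classes are never emitted.  What
the corpus does **not** emulate: mapping errors, agents/conditions,
stereochemistry, ring-forming chemistry, and the long tail of rare reaction
types — so green tests here demonstrate the machinery's correctness and
the workflow's behavior under controlled conditions, not performance on
patent-scale data.  Full-scale corpus results reported for such data
(reconstruction rates near 98%, ~11% valid decode rates, and specific
novelty tallies) require the original multi-million-reaction corpus and
GPU training and are out of desk-scale scope.

## Numerical and design notes

* All randomness flows from explicit seeds; the pipeline expands one
  top-level seed into per-stage seeds (kept below 2³¹).
* Water balancing patches exactly one boron site; a +4 disbalance (two
  boron events) is deliberately a failure, matching the single-water rule.
* The signature hash width (64 bits) makes accidental collisions at
  desk-scale pool sizes vanishingly unlikely; the exemplar-string fallback
  makes even those harmless.
* The per-motif-maximum novelty rule for multistep CGRs, the RC+2 ring
  retention rule, and the valence table are package choices documented
  above; none is claimed to replicate any specific external toolkit.
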