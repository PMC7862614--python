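# SMILES/CGR dialect reference

A linear notation for condensed graphs of reaction (CGR): one pseudo-
molecule whose atoms and bonds carry a pair of states (reactant, product).
Ordinary molecules are the special case in which both states agree.

## Base grammar

OpenSMILES subset:

* organic-subset atoms written bare: `B C N O P S F Cl Br I` and aromatic
  `b c n o p s`;
* bracket atoms: `[El]`, `[El+]`, `[El-]`, `[El+2]`, aromatic lowercase
  (`[si]`, `[se]`), optional atom map `[El:7]`;
* bonds `- = # :`; a missing bond symbol means single, or aromatic between
  two aromatic atoms;
* branches `( )`, components `.`, ring closures `1`-`9` and `%nn`.

Deviations from Daylight SMILES, chosen for this dialect:

* bracket atoms carry **no hydrogen count**: implicit hydrogens always fill
  the lowest allowed valence from the shipped valence table, for bare and
  bracketed atoms alike (an `H` count found on input is accepted and
  ignored);
* stereochemistry and isotopes are not part of the dialect.

## Dynamic extensions

* **Dynamic bond** `[x>y]` in bond position; `x` = reactant order, `y` =
  product order, each of `. - = # :` where `.` means "no bond".
  `C[.>-]C` is a C-C bond being formed; `c[->.]Br` an aryl bromide C-Br
  bond being broken.
* **Dynamic atom charge** inside the bracket: `[N+>0]` (cation neutralized),
  `[C0>-]` (anion formed).  Single charges may omit the magnitude.
* **Dynamic radical**: `[C*]` static radical, `[C*>0]` radical quenched,
  `[C0>*]` radical formed.

## Semantics

* Parsing a string yields a CGR in which every atom is present on both
  sides.  Writing a CGR that contains one-sided atoms (an atom recorded on
  only one side of the source reaction) completes them: the attachment bond
  of a one-sided fragment is written as a dynamic broken/formed bond and
  its internal bonds as static.  This is a deliberate information loss —
  re-parsing interprets the departed fragment as a full product (with
  hydrogen-capped valences), reproducing the implicit-hydrogen imbalance
  such sketchily-recorded reactions show downstream.
* Canonical form: iterative neighborhood refinement over the atom
  invariant (element, per-side charge/radical/aromaticity/presence, degree,
  bond-pair profile), remaining ties broken by the lexicographically
  smallest output string.  Canonical output is invariant under renumbering
  of the atom map ids.
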