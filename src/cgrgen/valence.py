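"""Allowed-valence table and implicit-hydrogen accounting.

The table lists, per element and formal charge, the allowed total valences
(sum of bond orders plus implicit hydrogens).  Implicit hydrogens are never
stored on atoms: they are recomputed as the gap between the observed explicit
valence and the smallest allowed valence that accommodates it.  Aromatic
bonds contribute 1.5 to the explicit valence; the total is rounded half-down
so that a ring-fusion atom with three aromatic bonds (4.5) counts as 4 and a
plain aromatic CH (3.0) counts as 3.

A monoradical occupies one valence slot: the allowed valences of a radical
atom are each reduced by one.
"""

from __future__ import annotations

from .errors import UnsupportedElementError

# order symbols used throughout the package; absence of a bond is None
ORDER_VALUE = {"-": 1.0, "=": 2.0, "#": 3.0, ":": 1.5}
ORDER_SYMBOLS = ("-", "=", "#", ":")

#: element -> {formal charge -> tuple of allowed valences}
VALENCES: dict[str, dict[int, tuple[int, ...]]] = {
    "H": {0: (1,), 1: (0,), -1: (0,)},
    "B": {0: (3,), -1: (4,)},
    "C": {0: (4,), 1: (3,), -1: (3,)},
    "N": {0: (3,), 1: (4,), -1: (2,)},
    "O": {0: (2,), 1: (3,), -1: (1,)},
    "F": {0: (1,), -1: (0,)},
    "Si": {0: (4,)},
    "P": {0: (3, 5), 1: (4,)},
    "S": {0: (2, 4, 6), 1: (3, 5), -1: (1,)},
    "Se": {0: (2, 4, 6)},
    "Cl": {0: (1,), -1: (0,)},
    "Br": {0: (1,), -1: (0,)},
    "I": {0: (1, 3), -1: (0,)},
    # common metals: closed-shell counts only; no implicit hydrogens expected
    "Li": {0: (1,), 1: (0,)},
    "Na": {0: (1,), 1: (0,)},
    "K": {0: (1,), 1: (0,)},
    "Mg": {0: (2,), 2: (0,)},
    "Zn": {0: (2,), 2: (0,)},
    "Cu": {0: (1, 2)},
    "Pd": {0: (0, 2)},
    "Sn": {0: (2, 4)},
}

SUPPORTED_ELEMENTS = frozenset(VALENCES)

#: elements writable without brackets when uncharged/non-radical (OpenSMILES
#: organic subset)
ORGANIC_SUBSET = frozenset({"B", "C", "N", "O", "P", "S", "F", "Cl", "Br", "I"})

#: elements that may carry the aromatic flag
AROMATIC_ELEMENTS = frozenset({"B", "C", "N", "O", "P", "S", "Se", "Si"})


def allowed_valences(element: str, charge: int = 0, radical: bool = False) -> tuple[int, ...]:
    """Allowed total valences for an element/charge/radical combination."""
    try:
        per_charge = VALENCES[element]
    except KeyError:
        raise UnsupportedElementError(f"unsupported element {element!r}") from None
    vals = per_charge.get(charge)
    if vals is None:
        # fall back to the neutral row shifted by the charge magnitude is not
        # chemically safe; unknown charge states are simply unparameterized
        raise UnsupportedElementError(
            f"no valence entry for {element} with charge {charge:+d}"
        )
    if radical:
        vals = tuple(max(v - 1, 0) for v in vals)
    return vals


def round_valence(value: float) -> int:
    """Round an explicit valence half-down (4.5 -> 4, 3.0 -> 3)."""
    return int(value + 0.5 - 1e-9)


def implicit_hydrogen_count(element, charge, radical, explicit_valence):
    """Implicit hydrogens filling the lowest allowed valence, or None.

    Returns None when no allowed valence accommodates the observed explicit
    valence (a violation, reported by the caller).
    """
    observed = round_valence(explicit_valence)
    for v in sorted(allowed_valences(element, charge, radical)):
        if v >= observed:
            return v - observed
    return None
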