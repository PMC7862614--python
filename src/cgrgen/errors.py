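"""Exception hierarchy shared across the package."""


class CGRGenError(Exception):
    """Base class for all package errors."""


class MappingError(CGRGenError):
    """Atom-to-atom mapping is inconsistent (duplicate or disjoint map ids)."""


class UnsupportedElementError(CGRGenError):
    """Element outside the supported valence table."""


class ValenceError(CGRGenError):
    """One or more atoms violate the allowed-valence table."""

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__("; ".join(str(v) for v in self.violations))


class SmilesSyntaxError(CGRGenError):
    """Malformed SMILES/CGR string; carries the offending position."""

    def __init__(self, message, position=None):
        self.position = position
        if position is not None:
            message = f"{message} (position {position})"
        super().__init__(message)


class EmptyReactionError(CGRGenError):
    """Reaction string with no reactants or no products."""


class VocabularyError(CGRGenError):
    """Token absent from the fixed vocabulary."""


class LengthError(CGRGenError):
    """Token sequence longer than the configured maximum length."""


class ArgumentError(CGRGenError):
    """Arguments inconsistent with the model or graph they refer to."""


class NoReactionCenterError(CGRGenError):
    """Operation requires at least one reaction center."""


class BalanceFailure(CGRGenError):
    """Reaction cannot be balanced by the single-water correction."""


class MissingBondEnergyError(CGRGenError):
    """Bond-energy table has no entry for an element pair / order."""


class ConfigError(CGRGenError):
    """Invalid configuration object."""


class DataError(CGRGenError):
    """Empty or unusable data set."""


class DegenerateDataError(CGRGenError):
    """Data without enough variance to fit a manifold."""


class EmptyZoneError(CGRGenError):
    """No map node satisfies the zone-selection thresholds."""
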