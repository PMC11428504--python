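"""Exception hierarchy.

All package errors derive from :class:`RadScavError` so callers can catch one
base class; subclasses mark the stage and failure mode.
"""


class RadScavError(Exception):
    """Base class for all radscav errors."""


class InvalidInputError(RadScavError, ValueError):
    """A scalar or field value violates a precondition (non-finite, wrong sign...)."""


class ParseError(RadScavError, ValueError):
    """A delimited-text input could not be validated.

    Parameters
    ----------
    message : str
    rows : sequence of int, optional
        1-based data-row numbers (header excluded) of the offending records.
    """

    def __init__(self, message, rows=None):
        self.rows = tuple(rows) if rows else ()
        if self.rows:
            message = f"{message} (rows {', '.join(map(str, self.rows))})"
        super().__init__(message)


class DuplicateKeyError(ParseError):
    """Two species records share the (compound, role, site, phase, spin) key."""


class OrphanSpeciesError(ParseError):
    """A derived species (radical/anion/radical cation) has no parent record."""


class SpeciesNotFoundError(RadScavError, KeyError):
    """No species record matches the requested key."""

    def __str__(self):  # KeyError quotes its arg; keep the plain message
        return self.args[0] if self.args else ""


class AmbiguousSpinError(RadScavError, LookupError):
    """Several spin states match and none was requested explicitly."""


class RoleMismatchError(InvalidInputError):
    """A species with the wrong role was passed to a descriptor equation."""


class PhaseMismatchError(InvalidInputError):
    """Species from different phases were combined in one equation."""


class NotComputableError(RadScavError):
    """A requested summary cannot be formed from the rows present."""


class ConstructibilityError(RadScavError, ValueError):
    """Synthetic targets are mutually inconsistent and admit no species set."""
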