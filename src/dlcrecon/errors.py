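"""Exception hierarchy shared across the package.

Every domain error derives from :class:`DLCError` so callers (and the CLI)
can separate contract violations from programming errors.
"""


class DLCError(Exception):
    """Base class for all domain errors raised by dlcrecon."""


class NewickParseError(DLCError, ValueError):
    """Malformed newick input; carries the 0-based offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class ArityError(DLCError, ValueError):
    """A tree node has a number of children other than 0 or 2."""


class UnknownNodeError(DLCError, KeyError):
    """A node id was looked up that is not present in the tree."""


class CoverageError(DLCError, ValueError):
    """A map that must be total is missing entries; carries the missing ids."""

    def __init__(self, message: str, missing=()):
        super().__init__(message)
        self.missing = tuple(missing)


class ConstraintError(DLCError, ValueError):
    """A structural precondition (e.g. species-map constraints 1-2) fails."""


class ValidationError(DLCError, ValueError):
    """An LCT failed validation; carries the violation records."""

    def __init__(self, violations):
        self.violations = list(violations)
        detail = "; ".join(str(v) for v in self.violations)
        super().__init__(f"invalid labeled coalescent tree: {detail}")


class SizeError(DLCError, ValueError):
    """An instance exceeds a desk-scale solver guard (guards are errors,
    never silent truncation)."""


class FormatError(DLCError, ValueError):
    """Malformed structured text input (DIMACS, map files, bundles)."""


class EmptyFormulaError(FormatError):
    """A CNF formula is empty after normalization."""


class ConfigError(DLCError, ValueError):
    """An impossible or inconsistent parameter combination."""


class UnsatisfiedClauseError(DLCError, ValueError):
    """A valuation leaves a clause unsatisfied where satisfaction is required."""

    def __init__(self, clause_index: int):
        super().__init__(f"clause {clause_index} is not satisfied by the valuation")
        self.clause_index = clause_index


class InconsistencyError(DLCError, ValueError):
    """A placement cannot be interpreted as a valuation (bad input solution)."""


class OccurrenceBoundError(DLCError, ValueError):
    """A formula violates a user-supplied per-variable occurrence bound."""
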