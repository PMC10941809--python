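"""Exception hierarchy for ontoburst.

All library errors derive from :class:`OntoburstError` so callers (and the
CLI) can catch a single base type.
"""

from __future__ import annotations


class OntoburstError(Exception):
    """Base class for all ontoburst errors."""


class MalformedCodeError(OntoburstError):
    """A positional ontology code does not match its grammar."""

    def __init__(self, code: str, reason: str = ""):
        self.code = code
        msg = f"malformed code {code!r}"
        if reason:
            msg += f": {reason}"
        super().__init__(msg)


class DuplicateCodeError(OntoburstError):
    """The same code appears more than once in one input."""

    def __init__(self, codes):
        self.codes = sorted(set(codes))
        super().__init__(f"duplicate code(s): {', '.join(self.codes)}")


class ValidationError(OntoburstError):
    """A data cell failed validation; carries the offending row number."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)


class FormatError(OntoburstError):
    """A file or stream does not conform to its declared format."""


class CycleError(OntoburstError):
    """The is_a graph of an OBO ontology contains a cycle."""

    def __init__(self, member: str):
        self.member = member
        super().__init__(f"cyclic is_a graph involving term {member!r}")


class EmptyInputError(OntoburstError):
    """An operation received an empty table, forest or layout."""


class ConfigError(OntoburstError):
    """A configuration value is out of its allowed domain."""
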