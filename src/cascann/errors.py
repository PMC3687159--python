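"""Exception hierarchy shared across the package."""


class CascannError(Exception):
    """Base class for all package-specific errors."""


class ParseError(CascannError):
    """A file could not be parsed (malformed cell, bad header, ...)."""


class ConsistencyError(CascannError):
    """Two inputs that must agree do not (e.g. matrix vs. metadata)."""


class ValidationError(CascannError):
    """A domain object violates one of its invariants."""


class CascadeExcluded(CascannError):
    """A cascade was rejected by one of the structural exclusion rules.

    Carries a human-readable ``reason``.
    """

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


class DependencyError(CascannError):
    """A pipeline stage was requested before its prerequisite ran."""
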