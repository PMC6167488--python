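"""Exception hierarchy.

Every error raised by the package derives from :class:`OmegaAccessError`, so
callers (and the CLI) can separate pipeline failures (exit code 1) from usage
and configuration mistakes (exit code 2).
"""


class OmegaAccessError(Exception):
    """Base class for all package errors."""


class ParseError(OmegaAccessError):
    """A structure or table file could not be parsed; carries a line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"{message} (line {line_number})"
        super().__init__(message)


class TopologyError(OmegaAccessError):
    """Atom layout violates the constant-topology contract of a trajectory."""


class ConfigurationError(OmegaAccessError):
    """A user-supplied configuration (site YAML, torsion bins) is invalid."""


class ContractError(OmegaAccessError):
    """An operation was called with inputs violating its documented contract."""


class DegenerateGeometryError(OmegaAccessError):
    """Coordinates too close to a geometric degeneracy (zero ray, planar center)."""
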