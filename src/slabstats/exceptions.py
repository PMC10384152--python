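"""Exception hierarchy.

Errors are split by what the caller can do about them: fix the input file
(:class:`ParseError`, :class:`StructuralError`), fix the call
(:class:`ArgumentError`), fix the topology annotation (:class:`TopologyError`,
:class:`RoleError`), or accept that the data cannot support the estimate
(:class:`NoValleyError`, :class:`ProfileShapeError`, :class:`FitError`).
"""


class SlabstatsError(Exception):
    """Base class for all package errors."""


class ParseError(SlabstatsError):
    """A text record could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class StructuralError(SlabstatsError):
    """File-level inconsistency (e.g. atom-count header mismatch)."""


class ArgumentError(SlabstatsError, ValueError):
    """Invalid argument values (non-positive box, bad ranges, ...)."""


class GeometryError(SlabstatsError):
    """Degenerate geometry: collinear torsion atoms, zero-length vectors."""


class CapacityError(SlabstatsError):
    """Requested composition does not fit the available interface area."""


class TopologyError(SlabstatsError):
    """Missing bonds/dihedrals or an atom that violates topology assumptions."""


class RoleError(TopologyError):
    """A required atom role label is absent."""


class FitError(SlabstatsError):
    """Nonlinear fit failed to converge; carries the best residual norm."""

    def __init__(self, message: str, residual_norm: float | None = None):
        self.residual_norm = residual_norm
        super().__init__(message)


class NoValleyError(SlabstatsError):
    """g(r) has no resolvable first minimum after its first peak."""


class ProfileShapeError(SlabstatsError):
    """Density profile lacks a bulk plateau or never crosses 10%/90%."""


class ModelError(SlabstatsError):
    """Element not covered by the promolecular density table."""


class ConfigError(SlabstatsError):
    """Pipeline configuration is invalid."""
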