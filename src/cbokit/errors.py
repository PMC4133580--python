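"""Exception hierarchy for cbokit.

All toolkit errors derive from :class:`CBOError` so callers can catch one
base class; subclasses mirror the failure modes of the individual layers
(ontology dialect, meta-model construction, VTK IO, snapshot semantics).
"""


class CBOError(Exception):
    """Base class for all cbokit errors."""


class UnresolvedClassError(CBOError, KeyError):
    """A CURIE or class name does not resolve in the hierarchy."""


class ManchesterParseError(CBOError):
    """Malformed block in the constrained Manchester dialect."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class DialectError(ManchesterParseError):
    """Well-formed syntax but illegal semantics for the dialect, e.g. a
    literal in an object-relation position."""


class SerializationError(CBOError):
    """Fragment cannot be rendered in the Manchester dialect."""


class QualityAbsentError(CBOError, LookupError):
    """No quality of the requested class attached to an individual."""


class AmbiguousQualityError(CBOError):
    """More than one actual value found for a quality class."""


class UnitError(CBOError, ValueError):
    """Unknown unit, or unit of the wrong dimension."""


class DomainError(CBOError, ValueError):
    """Degenerate spatial domain (non-positive extent, zero time step...)."""


class ConflictError(CBOError, ValueError):
    """Duplicate prototype name or VTK TypeID."""


class IncompleteError(CBOError, ValueError):
    """A prototype is missing a required field (e.g. corpuscular TypeID)."""


class ReferenceError_(CBOError, KeyError):
    """A process names an undeclared prototype."""


class ArityError(CBOError, ValueError):
    """Participant count does not match the process class."""


class ConventionError(CBOError, ValueError):
    """File name violates the `<root>_<digits>.vtk` series convention."""


class VTKFormatError(CBOError, ValueError):
    """Unsupported or malformed legacy-VTK content."""


class TruncationError(VTKFormatError):
    """Array entry count disagrees with the declared DIMENSIONS."""


class SeriesIncompleteError(CBOError):
    """Snapshot series lacks its zero-index initial file."""


class InconsistencyError(CBOError, ValueError):
    """A cell id carries more than one cell type across its voxels."""


class MappingError(CBOError, KeyError):
    """A snapshot TypeID has no prototype in the meta-model."""


class StabilityError(CBOError, ValueError):
    """Explicit diffusion stability bound D*dt/h^2 <= 1/6 violated."""


class ValidationError(CBOError):
    """Export refused because the meta-model has violations."""

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__(
            "meta-model has violations: "
            + "; ".join(f"{v.code}: {v.message}" for v in self.violations)
        )


class ResolutionError(CBOError, KeyError):
    """An annotation term path does not resolve in the hierarchy."""
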