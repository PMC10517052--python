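"""Exception hierarchy.

Every error raised by the package derives from :class:`PahemoError` so
callers (and the CLI, which maps these onto exit code 2/3) can catch the
package's failures without catching programming errors.
"""


class PahemoError(Exception):
    """Base class for all pahemo errors."""


class ValidationError(PahemoError):
    """Bad user input: domains, schemas, configuration (CLI exit code 2)."""


class DomainError(ValidationError):
    """A value is outside the mathematical domain of an operation."""


class ConfigurationError(ValidationError):
    """Missing or inconsistent configuration (tables, labels, options)."""


class FormatError(ValidationError):
    """A file could not be parsed as the expected format."""


class MeshIntegrityError(PahemoError):
    """Mesh fails a structural requirement (watertightness, labels)."""


class ConnectivityError(PahemoError):
    """A target is unreachable inside the meshed domain."""


class DegeneracyError(PahemoError):
    """Geometrically degenerate input (collinear points, zero-length axis)."""


class PlacementError(PahemoError):
    """Device pose does not intersect or abut the lumen."""


class GeometryError(PahemoError):
    """A geometric construction failed (self-intersection, Boolean failure)."""


class ConstraintError(ValidationError):
    """An infeasible constraint set; the message names the violated relation."""


class NumericError(PahemoError):
    """Numerical evaluation failed (overflow, non-convergence) (exit code 3)."""


class ProbePlacementError(PahemoError):
    """A pressure probe station falls outside the meshed domain."""
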