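"""Exception hierarchy shared across the package."""


class CorollaFoldError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(CorollaFoldError, ValueError):
    """A physical or configuration parameter violates its domain."""


class GeometryError(CorollaFoldError, ValueError):
    """Invalid, degenerate or self-intersecting geometry."""


class FormatError(CorollaFoldError, ValueError):
    """Malformed input file (outline CSV, config JSON, ...)."""


class ConstraintError(CorollaFoldError, RuntimeError):
    """Boundary conditions leave the elastic system singular."""


class NumericalError(CorollaFoldError, RuntimeError):
    """A solve produced non-finite or unacceptably inaccurate results."""


class ElementInversionError(NumericalError):
    """A triangle inverted (non-positive Jacobian) during growth.

    Carries the offending element index and, when known, the growth step.
    """

    def __init__(self, element: int, step: int | None = None):
        self.element = int(element)
        self.step = step
        where = f" at growth step {step}" if step is not None else ""
        super().__init__(f"element {element} inverted (det F <= 0){where}")


class ConfigurationError(CorollaFoldError, ValueError):
    """Inconsistent run configuration (empty friction band, empty load segment, ...)."""
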