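"""Exception hierarchy used across the package."""


class TomoregError(Exception):
    """Base class for all package-specific errors."""


class UsageError(TomoregError):
    """A caller violated an interface contract (bad flag, bad argument)."""


class GeometryError(TomoregError):
    """Incompatible or inconsistent image geometry."""


class DegenerateInputError(TomoregError):
    """Input is structurally valid but empty/degenerate for the operation."""


class DomainError(TomoregError):
    """A physical point lies outside the domain where a transform is defined."""


class DegenerateSamplingError(TomoregError):
    """Too few usable metric samples (excessive misalignment or over-cropping)."""


class ConvergenceFailure(TomoregError):
    """Optimizer failed to converge; carries the best transform found so far."""

    def __init__(self, message, best=None, diagnostics=None):
        super().__init__(message)
        self.best = best
        self.diagnostics = diagnostics or {}
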