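"""Exception hierarchy used across the package."""


class TnirsimError(Exception):
    """Base class for all package-specific errors."""


class DomainError(TnirsimError, ValueError):
    """A physical quantity is outside its valid range (negative mu_s, g > 1, ...)."""


class DegenerateMediumError(TnirsimError, ValueError):
    """Optical medium with no interaction (mu_a + mu_s' = 0)."""


class ConfigurationError(TnirsimError, ValueError):
    """Missing or inconsistent configuration (unknown tissue, chromophore, wavelength)."""


class ResolutionError(TnirsimError, ValueError):
    """Grid spacing too coarse to resolve a phantom layer."""


class GeometryError(TnirsimError, ValueError):
    """Shape mismatch or a cutline/source outside the grid."""


class SolverError(TnirsimError, RuntimeError):
    """Singular or otherwise unsolvable discrete system."""


class ConvergenceError(SolverError):
    """Iterative solve stopped above the requested residual tolerance."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class TableIntegrityError(TnirsimError, RuntimeError):
    """Packaged reference table does not match its recorded checksum."""
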