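"""Exception hierarchy used across the package."""


class OximetricError(Exception):
    """Base class for all package errors."""


class ValidationError(OximetricError, ValueError):
    """Malformed or out-of-contract input."""


class CoverageError(ValidationError):
    """A wavelength grid falls outside the tabulated chromophore coverage."""


class IsosbesticNotFoundError(OximetricError):
    """The oxy/deoxy difference does not change sign inside the search window."""


class DegenerateSpectrumError(OximetricError):
    """A spectrum cannot be normalized (zero mean) or is identically zero."""


class DegenerateFitError(OximetricError):
    """The two-chromophore least-squares fit has no defined SO2 (c1 + c2 = 0)."""


class DegenerateClusterError(OximetricError):
    """A slope-pair cluster has (numerically) zero spread; the ratio is undefined."""


class NearFieldError(OximetricError):
    """A fluence evaluation point is too close to the source for the point-source
    diffusion approximation to be valid."""


class ConfigError(OximetricError):
    """Inconsistent run configuration (e.g. energy normalization requested
    without recorded pulse energies)."""
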