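"""Exception hierarchy."""


class LinacQAError(Exception):
    """Base class for all package errors."""


class DegenerateGeometryError(LinacQAError):
    """A geometric construction is ill-posed (parallel lines/planes, rank loss, ...)."""


class ConfigurationError(LinacQAError):
    """Invalid user configuration (bad units, out-of-range values, schema errors)."""


class VisibilityError(LinacQAError):
    """A marker does not project onto the detector / radiation field."""


class ReconstructionError(LinacQAError):
    """A geometry solver failed (under-determined data, non-convergence)."""
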