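"""Exception hierarchy shared by all skinmech modules."""


class SkinMechError(Exception):
    """Base class for all skinmech errors."""


class InvalidGeometryError(SkinMechError, ValueError):
    """Non-positive pad width or skin thickness in a stress conversion."""


class InvalidParameterError(SkinMechError, ValueError):
    """Rheological parameters violate their invariants (e.g. sum(p_i) >= 1)."""


class InvalidInputError(SkinMechError, ValueError):
    """Malformed input series (unsorted time grid, mismatched lengths, ...)."""


class InsufficientDataError(SkinMechError, ValueError):
    """Fewer samples than free parameters in a fit window."""


class InsufficientSignalError(SkinMechError, ValueError):
    """Fit rejected because the record carries no usable signal."""


class NoLinearPhaseError(SkinMechError, ValueError):
    """No window of a loading curve meets the linearity threshold."""


class UndefinedCentroidError(SkinMechError, ValueError):
    """Spectral centroid undefined (no off-DC energy, e.g. constant image)."""


class UndefinedRatioError(SkinMechError, ZeroDivisionError):
    """Poisson's ratio undefined because the axial strain is zero."""


class InvalidSpecError(SkinMechError, ValueError):
    """A synthetic-data specification violates its invariants."""
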