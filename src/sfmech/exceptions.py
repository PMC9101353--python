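"""Exception and warning hierarchy."""


class SfmechError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(SfmechError, ValueError):
    """A physical parameter violates its admissible range."""


class ModelValidityError(SfmechError, ValueError):
    """Inputs are inside numeric range but outside the model's validity."""


class NumericalError(SfmechError, RuntimeError):
    """A root solve or integration failed; carries diagnostics."""


class IntegrationError(NumericalError):
    """Forward integration produced a non-finite state."""

    def __init__(self, message, last_valid_time=None):
        super().__init__(message)
        self.last_valid_time = last_valid_time


class DegenerateGeometryError(SfmechError, ValueError):
    """Geometry input admits no finite solution (e.g. collinear points)."""


class KymographStateError(SfmechError, ValueError):
    """Operation applied to a kymograph in the wrong normalization state."""


class CorrectionFailureError(SfmechError, RuntimeError):
    """Photobleaching correction produced a non-physical decay constant."""


class SfmechWarning(UserWarning):
    """Base class for package warnings."""


class StrainRangeWarning(SfmechWarning):
    """Strain magnitude outside the experimentally explored range."""


class MultiRootWarning(SfmechWarning):
    """The implicit rate equation had several roots; continuation was used."""


class DomainWarning(SfmechWarning):
    """Expression evaluated outside the branch it models (value clamped)."""


class LandmarkAmbiguityWarning(SfmechWarning):
    """Intensity profile has no clear peak/valley structure."""


class IdentifiabilityWarning(SfmechWarning):
    """Fitted parameters lie on a flat ridge of the objective."""
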