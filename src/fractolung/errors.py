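"""Exception hierarchy."""


class FractolungError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FractolungError):
    """Invalid parameters, specs, or config files."""


class GeometryError(FractolungError):
    """Mismatched grid dimensions or spacings."""


class VolumeReadError(FractolungError):
    """A CT volume or mask could not be read (missing slices, bad modality...)."""


class UndefinedMetricError(FractolungError):
    """A metric has no defined value on this input (e.g. empty mask)."""


class DegenerateEstimateError(FractolungError):
    """A dimension estimate is outside its valid domain.

    Carries the raw log-log slope in ``slope``.
    """

    def __init__(self, message: str, slope: float):
        super().__init__(message)
        self.slope = slope


class DegenerateLabelsError(FractolungError):
    """Modeling input contains a single outcome class."""


class GenerationError(FractolungError):
    """A synthetic generator could not realize a requested constraint."""
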