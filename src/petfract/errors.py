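"""Exception hierarchy for the petfract pipeline."""


class PetfractError(Exception):
    """Base class for all petfract errors."""


class VolumeLoadError(PetfractError):
    """Raised when a DICOM series or raw volume container cannot be loaded."""


class FixtureLoadError(PetfractError):
    """Raised when a cohort fixture table is missing, empty or has the
    wrong schema."""


class FitError(PetfractError):
    """Raised when a power-law fit cannot be performed (too few scales,
    zero counts inside the fit range, ...)."""


class AnalysisError(PetfractError):
    """Raised when a measure is requested on degenerate input
    (zero tracer mass, missing baseline stage, empty cohort, ...)."""


class GenerationError(PetfractError):
    """Raised when a phantom cannot be generated under its constraints."""
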