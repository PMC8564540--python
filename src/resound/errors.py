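"""Exception types shared across the pipeline."""


class ResoundError(Exception):
    """Base class for all package errors."""


class ParameterError(ResoundError, ValueError):
    """An argument or configuration value violates its contract."""


class NoRecordingsError(ResoundError):
    """No usable recordings exist for a species; its sites must be dropped."""

    def __init__(self, species_code: str, message: str | None = None):
        self.species_code = species_code
        super().__init__(message or f"no recordings available for species {species_code!r}")


class SilentClipError(ResoundError):
    """A clip with zero peak amplitude reached a stage that needs sound."""


class InclusionError(ResoundError, ValueError):
    """A record set fails the survey-inclusion rules (e.g. too few years)."""


class NoAnalyzableSitesError(ResoundError):
    """Every site was excluded by the inclusion filters."""


class FitError(ResoundError):
    """A statistical model could not be fitted (rank deficiency, divergence)."""
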