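"""Exception hierarchy.

Exit-code mapping in the CLI: ConfigurationError -> 2, everything else -> 1.
"""


class SitStandGoError(Exception):
    """Base class for package errors."""


class ConfigurationError(SitStandGoError):
    """Invalid user-supplied configuration or specification."""


class DegenerateInputError(SitStandGoError):
    """Input too short / too small for the requested computation."""


class UndefinedFeatureError(SitStandGoError):
    """A feature is mathematically undefined for this segment (e.g. zero turning angle)."""


class SubphaseNotFoundError(SitStandGoError):
    """A required subphase could not be located in the recording."""

    def __init__(self, subphase: str, message: str | None = None):
        self.subphase = subphase
        super().__init__(message or f"subphase not found: {subphase}")


class SchemaError(SitStandGoError):
    """A file does not conform to the documented CSV/JSON schema."""
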