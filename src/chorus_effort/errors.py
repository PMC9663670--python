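"""Exception types shared across the package."""


class ChorusEffortError(Exception):
    """Base class for package-specific errors."""


class SchemaError(ChorusEffortError):
    """Input table columns cannot be mapped to the expected schema."""


class GridValidationError(ChorusEffortError):
    """A record's offset or phase does not fit the sampling grid."""


class SunriseLookupError(ChorusEffortError, KeyError):
    """A required (plot, date) sunrise entry is missing."""


class NoSunriseError(ChorusEffortError):
    """The sun does not cross the horizon on the requested date (polar day/night)."""


class SchedulingWindowError(ChorusEffortError):
    """A scheduled cut falls outside the recorder's operating window."""
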