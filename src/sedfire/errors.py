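"""Exception hierarchy shared across the pipeline stages."""


class SedfireError(Exception):
    """Base class for all package-specific errors."""


class ChronologyError(SedfireError):
    """Degenerate or inconsistent age-depth information."""


class OutOfRangeError(ChronologyError):
    """Depth (or age) queried outside the modelled range."""


class UndefinedConcentrationError(SedfireError):
    """Zero tracer spores counted: concentration is unmeasurable, not zero."""


class CalibrationError(SedfireError):
    """Missing or invalid PAR-to-biomass calibration entry."""


class InputError(SedfireError):
    """Malformed or inconsistent user input."""
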