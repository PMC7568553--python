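"""Exception hierarchy shared across the package."""


class DiaHarmonyError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(DiaHarmonyError, ValueError):
    """A numeric or enumerated parameter is outside its admissible range."""


class SchemeMismatchError(DiaHarmonyError, ValueError):
    """The precursor m/z range cannot be tiled by the requested window layout."""


class MzRangeError(DiaHarmonyError, ValueError):
    """An m/z value falls outside the method's precursor range."""


class ReportFormatError(DiaHarmonyError, ValueError):
    """A report file violates the expected TSV dialect."""


class ManifestError(DiaHarmonyError, ValueError):
    """A run manifest is malformed or contains duplicate run keys."""


class ConfigError(DiaHarmonyError, ValueError):
    """A study or simulation configuration is inconsistent."""


class DegenerateInputError(DiaHarmonyError, ValueError):
    """An input collection is empty or degenerate where data is required."""
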