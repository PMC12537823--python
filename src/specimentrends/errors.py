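"""Exception hierarchy shared across the pipeline.

Configuration problems (bad column mappings, overlapping periods, invalid
smoothing spans) and data problems (negative counts, duplicate keys) are kept
distinct so the command-line layer can map them to different exit codes.
"""


class SpecimenTrendsError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(SpecimenTrendsError):
    """The requested operation was mis-configured (exit code 2 at the CLI)."""


class DataError(SpecimenTrendsError):
    """The input data violates a contract (exit code 3 at the CLI)."""


class UndefinedRatioError(DataError):
    """A ratio was requested with a zero denominator."""
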