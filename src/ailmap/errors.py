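"""Exception types shared across the pipeline."""


class AilmapError(Exception):
    """Base class for all package errors."""


class FormatError(AilmapError):
    """Malformed input file (missing columns, bad values); message names offending rows."""


class DuplicateMarkerError(FormatError):
    """Two records share the same (chrom, pos)."""


class ConfigurationError(AilmapError):
    """Invalid or incomplete run configuration."""


class ParameterError(AilmapError):
    """A numeric parameter is outside its valid range."""


class UndefinedResultError(AilmapError):
    """Requested summary is undefined for the given (e.g. empty) input."""
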