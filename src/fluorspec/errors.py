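"""Exception hierarchy."""


class FluorspecError(Exception):
    """Base class for all package errors."""


class FormatError(FluorspecError):
    """Malformed trajectory or spectrum file."""


class TopologyError(FluorspecError):
    """Missing or inconsistent masses, charges or molecule ids."""


class GeometryError(FluorspecError):
    """Degenerate geometry (collinear fit subset, coincident atoms...)."""


class InputError(FluorspecError):
    """Invalid argument values or array shapes."""


class ConfigError(FluorspecError):
    """Invalid generator or pipeline configuration."""


class AnalysisError(FluorspecError):
    """An analysis step cannot produce a meaningful result."""


class NormalizationError(AnalysisError):
    """Band normalization reference missing or degenerate."""
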