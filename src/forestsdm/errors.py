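"""Exception types shared across the pipeline."""


class ForestSDMError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ForestSDMError):
    """Invalid generator or pipeline configuration."""


class DataError(ForestSDMError):
    """Malformed input data (negative DBH, non-binary mask, non-finite feature...)."""


class InterfaceError(ForestSDMError):
    """Mismatch between spatial layers and point coordinates."""


class DegenerateSpeciesError(ForestSDMError):
    """A virtual species whose suitability is zero everywhere."""


class PipelineError(ForestSDMError):
    """A pipeline stage could not produce output (e.g. zero background points)."""
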