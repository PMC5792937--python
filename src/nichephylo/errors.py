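"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: ConfigError -> 1, DataError -> 2,
NumericalError -> 3.
"""


class NichephyloError(Exception):
    """Base class for all package errors."""


class ConfigError(NichephyloError):
    """Invalid or inconsistent configuration."""


class DataError(NichephyloError):
    """Malformed, missing or incompatible input data."""


class GeometryError(DataError):
    """Raster layers with incompatible grid geometry."""


class NumericalError(NichephyloError):
    """Optimisation or numerical failure."""
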