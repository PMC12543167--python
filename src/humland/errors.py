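"""Exception hierarchy.

All package errors derive from :class:`HumlandError`, which itself derives
from ``ValueError`` so callers that do not care about the distinction can
catch the standard type.
"""


class HumlandError(ValueError):
    """Base class for all errors raised by this package."""


class GridFormatError(HumlandError):
    """A raster file is malformed (bad header, ragged rows, ...)."""


class ConsistencyError(HumlandError):
    """Two objects that must agree (shapes, masks, cell counts) do not."""


class ConfigurationError(HumlandError):
    """A configuration value is invalid or internally inconsistent."""


class DomainError(HumlandError):
    """An input is outside the mathematical domain of an operation."""
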