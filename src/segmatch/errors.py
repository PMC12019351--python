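"""Exception hierarchy shared across the package."""


class SegmatchError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SegmatchError, ValueError):
    """A configuration value violates its contract."""


class GeometryError(SegmatchError, ValueError):
    """Shapes or coordinates are incompatible."""


class DataError(SegmatchError, ValueError):
    """Input data violates its contract (bad labels, bad files, ...)."""


class TrainingError(SegmatchError, RuntimeError):
    """Training produced a non-finite loss or otherwise diverged."""
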