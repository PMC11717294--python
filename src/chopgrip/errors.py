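"""Exception hierarchy.

Detection and feature failures that the pipeline is designed to absorb
(carry-forward, gap filling) are signalled with dedicated exception types so
callers can distinguish recoverable per-frame failures from hard errors.
"""


class ChopgripError(Exception):
    """Base class for all package errors."""


class ProtocolError(ChopgripError, ValueError):
    """Invalid trial protocol (e.g. fps below the Nyquist rate)."""


class ConfigurationError(ChopgripError, ValueError):
    """Invalid configuration (unknown predictor, empty class mix, ...)."""


class RenderError(ChopgripError, ValueError):
    """Frame geometry cannot be rasterized (frame too small, empty input)."""


class DetectionFailure(ChopgripError):
    """A single frame's chopstick detection failed (recoverable)."""


class FeatureFailure(ChopgripError):
    """A single frame's feature computation failed (triggers gap fill)."""


class GeometryError(ChopgripError, ValueError):
    """Degenerate geometry (zero-length segment, zero hand length)."""


class SequenceError(ChopgripError, ValueError):
    """A whole sequence is unusable (too short, all frames failed)."""


class ZeroVarianceError(ChopgripError, ValueError):
    """A statistic that requires variation was asked of a constant series."""


class SchemaError(ChopgripError, ValueError):
    """An input file does not match the documented schema."""


class FitError(ChopgripError, RuntimeError):
    """A statistical model failed to fit (non-convergence, separation)."""
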