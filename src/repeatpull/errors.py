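"""Exception hierarchy for repeatpull."""


class RepeatPullError(Exception):
    """Base class for all repeatpull errors."""


class FormatError(RepeatPullError):
    """Malformed input file (e.g. inconsistent atom count across models)."""


class DataError(RepeatPullError):
    """Well-formed file with inconsistent data (e.g. non-monotonic time)."""


class ConfigError(RepeatPullError):
    """Invalid configuration (repeat map, pipeline config, ...)."""


class GeometryError(RepeatPullError):
    """Coordinate/topology problem (missing atoms, too few for a fit)."""


class FitError(RepeatPullError):
    """A model fit failed or is degenerate."""


class ThresholdError(RepeatPullError):
    """No usable high-force tail for threshold selection."""


class NumericalError(RepeatPullError):
    """A numerical routine (root bracketing, ...) failed."""
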