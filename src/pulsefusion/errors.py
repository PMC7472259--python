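"""Exception hierarchy.

``ConfigurationError`` and ``DataFormatError`` signal user mistakes (bad
parameters, malformed files) and map to exit code 1 in the CLI; anything
else is treated as an internal error (exit code 2).
"""


class PulseFusionError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PulseFusionError, ValueError):
    """Invalid parameter or configuration value; names the offending field."""


class DataFormatError(PulseFusionError, ValueError):
    """Malformed input file (bad schema, NaNs, non-uniform timestamps...)."""


class SegmentError(PulseFusionError, ValueError):
    """A signal segment violates an operation's precondition."""
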