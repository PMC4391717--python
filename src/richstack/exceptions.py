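"""Exception hierarchy for richstack."""


class RichstackError(Exception):
    """Base class for all richstack errors."""


class FormatError(RichstackError):
    """A file does not conform to its declared format."""


class AlignmentError(RichstackError):
    """Two grids that must share geometry do not."""


class ConfigurationError(RichstackError):
    """An invalid parameter or layer-name configuration."""


class CapacityError(RichstackError):
    """A sample size exceeds the available population."""


class InputError(RichstackError):
    """Degenerate or insufficient input data."""
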