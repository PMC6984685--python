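"""Exception types shared across the package."""


class GenedivError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(GenedivError, ValueError):
    """Invalid or infeasible parameter combination."""


class InputError(GenedivError, ValueError):
    """Malformed or inconsistent user-supplied data."""


class DegenerateInputError(GenedivError, ValueError):
    """Data that makes a statistic undefined (e.g. zero pooled variance)."""


class EmptySampleError(GenedivError, ValueError):
    """A sample with no usable reads where a normalisation requires some."""
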