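"""Exception hierarchy.

Errors map onto CLI exit codes: parameter/usage errors (2), data and
format errors (3), estimation failures (4).
"""


class MRCorgeError(Exception):
    """Base class for all package errors."""


class ParameterError(MRCorgeError):
    """Invalid parameter or configuration value."""


class FormatError(MRCorgeError):
    """Malformed input file (missing columns, unparsable values)."""


class DataError(MRCorgeError):
    """Structurally valid input whose content is unusable
    (duplicate variants, empty instrument intersection, ...)."""


class EstimationError(MRCorgeError):
    """An estimator could not produce a result from the given records."""
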