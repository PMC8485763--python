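"""Exception hierarchy shared by all pipeline stages."""


class PolfidError(Exception):
    """Base class for all package errors."""


class ParameterError(PolfidError, ValueError):
    """A configuration or function parameter is outside its valid domain."""


class DataError(PolfidError, ValueError):
    """Input data violate a structural contract (shape, sign, emptiness)."""


class CalibrationError(PolfidError, ValueError):
    """Ladder peak detection or calibration fitting failed."""


class NumericalError(PolfidError, RuntimeError):
    """An optimization or root-finding step failed to converge."""
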