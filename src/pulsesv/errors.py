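class PulseSVError(Exception):
    """Base class for all package errors."""


class ValidationError(PulseSVError):
    """Invalid input data or configuration."""


class SolverError(PulseSVError):
    """The 1-D pulse solver could not produce a usable field."""
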