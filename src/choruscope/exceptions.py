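"""Exception hierarchy shared across the toolkit."""


class ChoruscopeError(Exception):
    """Base class for all toolkit errors."""


class InputError(ChoruscopeError, ValueError):
    """Raised when an input (file, signal, matrix) is unusable."""


class ParameterError(ChoruscopeError, ValueError):
    """Raised when a parameter combination is invalid."""


class UndefinedInputError(InputError):
    """Raised when a quantity is mathematically undefined for the given
    input (e.g. the spectral entropy of silence)."""
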