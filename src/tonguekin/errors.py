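"""Exception types shared across the package."""


class ParameterError(ValueError):
    """A configuration or function parameter is invalid."""


class InputError(ValueError):
    """An input array/table violates the operation's preconditions."""


class QualityError(RuntimeError):
    """A clip or trajectory fails quality control (e.g. too many missing frames)."""


class DegenerateAmplitudeError(ValueError):
    """Maximum amplitude below the guard threshold; the normalized ratio
    frequency / amplitude would be unstable."""


class StateError(RuntimeError):
    """Operation called in an invalid state (e.g. segmenting with an untrained model)."""


class MulticollinearityError(ValueError):
    """Design matrix is rank deficient; offending predictors are named in the message."""
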