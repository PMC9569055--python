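"""Exception hierarchy shared by all pipeline stages."""


class MspcdError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MspcdError, ValueError):
    """A file's content does not match the declared on-disk format."""


class ValidationError(MspcdError, ValueError):
    """A parsed artifact violates a structural invariant."""


class ParameterError(MspcdError, ValueError):
    """An argument is outside its documented domain."""


class CoverageError(MspcdError, KeyError):
    """An entity was requested from a source that does not cover it."""


class TrainingError(MspcdError, RuntimeError):
    """The training set cannot support model fitting."""
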