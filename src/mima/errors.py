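"""Exception hierarchy shared across the pipeline stages."""


class MimaError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MimaError):
    """A configuration value is missing or out of range; the message names the field."""


class DegenerateMatrixError(MimaError):
    """A matrix violates a precondition (e.g. all-zero abundances)."""


class DegenerateDesignError(MimaError):
    """A comparison design cannot support the requested test (e.g. a group with <2 samples)."""


class DegeneratePredictorError(MimaError):
    """A regression predictor is constant and carries no information."""


class AlignmentError(MimaError):
    """Sample identifiers of two matrices do not align."""


class FormatError(MimaError):
    """A file on disk does not follow the expected dialect; includes position context."""
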