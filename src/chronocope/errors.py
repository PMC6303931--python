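"""Exception hierarchy.

Every error raised by chronocope derives from :class:`ChronocopeError`, so
callers can catch one type at a pipeline boundary while tests can assert the
specific failure mode.
"""


class ChronocopeError(Exception):
    """Base class for all chronocope errors."""


class ConfigurationError(ChronocopeError):
    """Invalid cohort or run configuration (bad counts, unknown channel...)."""


class InputError(ChronocopeError):
    """Malformed input table (duplicate ids, mismatched lengths...)."""


class InsufficientDataError(ChronocopeError):
    """Too few observations for the requested statistic."""


class SingularDesignError(ChronocopeError):
    """Degenerate regression design (e.g. all times equal modulo 24 h)."""


class UndefinedStatisticError(ChronocopeError):
    """The statistic is undefined for this input (zero variance and the like)."""


class IncompleteDesignError(ChronocopeError):
    """A factorial/time-course design has missing cells; message lists gaps."""


class DegenerateRecordError(ChronocopeError):
    """A single behavioural record is internally inconsistent."""
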