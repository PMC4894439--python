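"""Exception hierarchy for pathq.

All package errors derive from :class:`PathQError` so callers can catch one
base class; each subclass also derives from the closest built-in so existing
``except ValueError`` style handling keeps working.
"""


class PathQError(Exception):
    """Base class for all pathq errors."""


class InvalidParameterError(PathQError, ValueError):
    """A model or function parameter is outside its admissible range."""


class MissingVariableError(PathQError, KeyError):
    """A required variable id is absent from the supplied data or state."""

    def __init__(self, missing, context=""):
        if isinstance(missing, str):
            missing = [missing]
        self.missing = sorted(missing)
        msg = f"missing variable(s): {', '.join(self.missing)}"
        if context:
            msg += f" ({context})"
        super().__init__(msg)


class InsufficientDataError(PathQError, ValueError):
    """Too few observations for the requested operation."""


class InfeasibleFitError(PathQError, ValueError):
    """Sample size does not exceed the number of parameters to fit."""


class IntegrationError(PathQError, RuntimeError):
    """ODE integration failed (blow-up or stiffness beyond budget)."""

    def __init__(self, message, last_valid_time=None):
        super().__init__(message)
        self.last_valid_time = last_valid_time


class DegreesOfFreedomError(PathQError, ValueError):
    """A denominator degree of freedom is non-positive."""


class PerfectFitError(PathQError, ValueError):
    """Residual sum of squares is zero; F-type statistics are undefined."""


class UndefinedAUCError(PathQError, ValueError):
    """ROC/AUC requested with only one class present."""


class GenerationError(PathQError, RuntimeError):
    """Random model generation exhausted its rejection budget."""


class ParseError(PathQError, ValueError):
    """A data file could not be parsed."""

    def __init__(self, message, path=None, line=None):
        loc = ""
        if path is not None:
            loc += str(path)
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)
        self.path = path
        self.line = line
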