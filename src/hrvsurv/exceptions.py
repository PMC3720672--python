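"""Exception hierarchy shared across the package.

Flags that are part of a result (an undefined odds ratio, a median the survival
curve never reaches, a cutpoint the smoother cannot bracket) are *not* raised;
they are carried on the result objects.  Exceptions are reserved for inputs the
operation cannot meaningfully process.
"""


class HrvSurvError(Exception):
    """Base class for all package errors."""


class InputError(HrvSurvError, ValueError):
    """Malformed or non-finite input data."""


class EmptySeriesError(HrvSurvError):
    """No beats could be recovered from a trace."""


class CoverageError(HrvSurvError):
    """A recording is too short for the requested analysis segment."""


class ValidityError(HrvSurvError, ValueError):
    """A value violates a physiological or structural invariant."""


class SchemaError(HrvSurvError, ValueError):
    """A table or configuration does not match its published schema."""


class StageError(HrvSurvError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
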