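"""Exception hierarchy shared across the package."""


class MicrosojournError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(MicrosojournError, ValueError):
    """Invalid model or scheme parameters (e.g. sigma >= 2: no stationary gamma)."""


class IntegrationError(MicrosojournError, RuntimeError):
    """Non-finite state encountered during SDE integration; message names the step."""


class CompositionError(MicrosojournError, ValueError):
    """Relative abundances not a valid composition for multinomial sampling."""


class NoSignalError(MicrosojournError, ValueError):
    """All read counts are zero: abundance parameters are unidentifiable."""


class FitFailureError(MicrosojournError, RuntimeError):
    """Likelihood optimisation failed from every starting point."""


class InsufficientDataError(MicrosojournError, ValueError):
    """Too few observations for the requested operation."""


class EmptySummaryError(MicrosojournError, ValueError):
    """No run lengths available to summarise."""


class MissingTError(MicrosojournError, ValueError):
    """No sojourn trajectory with the requested duration T."""


class UndefinedCorrelationError(MicrosojournError, ValueError):
    """Rank correlation undefined because one variable is constant."""


class PipelineError(MicrosojournError, RuntimeError):
    """A pipeline stage failed; message carries the stage and offending ASV."""
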