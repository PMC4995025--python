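"""Exception hierarchy shared across the package."""


class ScoreMrError(Exception):
    """Base class for all scoremr errors."""


class ConfigError(ScoreMrError, ValueError):
    """Invalid configuration: missing columns, bad cutpoints, bad schema."""


class ParseError(ScoreMrError, ValueError):
    """A data row could not be parsed or violates a field invariant."""


class DomainError(ScoreMrError, ValueError):
    """Mathematically invalid input (non-positive SE, undefined ratio, ...)."""


class InsufficientDataError(ScoreMrError, ValueError):
    """Too few inputs for the requested statistic (e.g. Q with k < 2)."""


class DegenerateFitError(ScoreMrError, RuntimeError):
    """A model fit is degenerate: zero variance, separation, non-convergence."""
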