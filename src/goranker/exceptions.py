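"""Exception hierarchy.

All goranker errors derive from :class:`GorankerError` so callers can catch
library failures without masking programming errors.
"""


class GorankerError(Exception):
    """Base class for all goranker errors."""


class ParseError(GorankerError):
    """A file could not be parsed (OBO, GAF, tabular input)."""


class ValidationError(GorankerError):
    """An input violated a documented precondition or type invariant."""


class ConfigError(GorankerError):
    """An invalid configuration value (dates out of order, top_k < 1, ...)."""


class FitError(GorankerError):
    """A model could not be fitted (e.g. empty training corpus)."""


class EvaluationError(GorankerError):
    """A metric is undefined on the given inputs (empty truth, no positives)."""
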