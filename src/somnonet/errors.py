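"""Exception hierarchy for the somnonet pipeline.

Everything derives from :class:`SomnonetError` so callers can catch pipeline
failures without swallowing genuine bugs.  Per-stage failures inside the
cohort orchestrator are recorded, not raised, so a single unusable
subject-stage never aborts a whole cohort run.
"""


class SomnonetError(Exception):
    """Base class for all somnonet errors."""


class InvalidParameterError(SomnonetError, ValueError):
    """A parameter violates an operation's precondition."""


class InsufficientDataError(SomnonetError):
    """Too few clean scoring epochs (or samples) for the requested analysis."""


class StabilityError(SomnonetError):
    """A constructed or estimated VAR model could not be stabilized."""


class EstimationError(SomnonetError):
    """Model estimation failed (rank-deficient regressors, unstable fit...)."""


class SpectralError(SomnonetError):
    """Spectral evaluation failed (singular transfer function, etc.)."""


class UndefinedMetricError(SomnonetError):
    """A network metric is undefined for this graph (e.g. no connected pairs)."""


class FormatError(SomnonetError):
    """An input file does not satisfy the expected format/montage contract."""
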