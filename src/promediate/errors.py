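"""Exception hierarchy for the mediation pipeline.

Errors are grouped so the CLI can map them onto distinct exit codes:
configuration problems, data/transcript problems, and sampler/study failures.
"""


class PromediateError(Exception):
    """Base class for all package errors."""


class ConfigError(PromediateError):
    """Invalid configuration value or malformed config file."""


class TranscriptError(PromediateError):
    """Base class for transcript parsing problems."""


class IncompleteTranscriptError(TranscriptError):
    """A required router node is missing from the transcript."""


class AmbiguousAnswerError(TranscriptError):
    """A severity answer contains more than one numeric token."""


class AnswerParseError(TranscriptError):
    """A severity answer contains no parseable number."""


class IntegrityError(PromediateError):
    """Cohort-level consistency violation (e.g. duplicate subject IDs)."""


class DegenerateDesignError(PromediateError):
    """Only one treatment arm present: the exposure effect is unidentifiable."""


class RankDeficiencyError(PromediateError):
    """Collinear design columns (e.g. a constant covariate)."""


class ConvergenceError(PromediateError):
    """MCMC chains failed the convergence diagnostic."""


class StudyFailureError(PromediateError):
    """The simulation study produced no usable (converged) replications."""
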