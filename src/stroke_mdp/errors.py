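"""Exception hierarchy.

``InputError``/``ConfigurationError`` indicate problems a user can fix in
their data or config (CLI exit code 1); everything else escaping the CLI is
treated as an internal error (exit code 2).
"""


class StrokeMDPError(Exception):
    """Base class for all package errors."""


class ConfigurationError(StrokeMDPError):
    """A config file, column map or schema is wrong or incomplete."""


class InputError(StrokeMDPError):
    """A data file violates the cohort contract (bad cell, duplicate id...)."""


class ValidationError(StrokeMDPError):
    """A value violates a domain invariant (alphabet, score range...)."""


class ImputationError(StrokeMDPError):
    """A gap has no non-missing neighbours within the imputation window."""


class RecordRejected(StrokeMDPError):
    """A record cannot yield episodes; carries a short machine-readable reason."""

    def __init__(self, reason: str, detail: str = ""):
        self.reason = reason
        super().__init__(f"{reason}: {detail}" if detail else reason)


class SolverError(StrokeMDPError):
    """The fitted model cannot be solved (e.g. empty admissible set)."""


class EvaluationError(StrokeMDPError):
    """A policy cannot be evaluated from the requested state."""


class OracleError(StrokeMDPError):
    """The brute-force enumeration oracle refuses an oversized instance."""


class ReportingError(StrokeMDPError):
    """A requested report cannot be produced from the given solution."""
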