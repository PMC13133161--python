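"""Exception hierarchy for fedsurv.

Every error raised by the package derives from :class:`FedsurvError`, so
callers can catch one type at a pipeline boundary while tests can assert
the specific failure mode.
"""


class FedsurvError(Exception):
    """Base class for all fedsurv errors."""


class InvalidInputError(FedsurvError, ValueError):
    """An argument violates a documented precondition."""


class DataConsistencyError(FedsurvError, ValueError):
    """A patient record contradicts itself (e.g. event after last follow-up)."""


class EncodingError(FedsurvError, ValueError):
    """A categorical field holds a level outside the data dictionary."""


class ImputationError(FedsurvError, ValueError):
    """Federated imputation cannot proceed (no donor centre has data)."""


class ContractError(FedsurvError, ValueError):
    """A cross-module contract is violated (dimension or grid mismatch)."""


class ConfigError(FedsurvError, ValueError):
    """A run or simulation configuration is infeasible."""


class NoEventsError(FedsurvError, ValueError):
    """No events anywhere in the federation: the partial likelihood is flat."""


class SeparationError(FedsurvError, RuntimeError):
    """Monotone partial likelihood: a coefficient diverges without the
    score vanishing."""


class ConvergenceError(FedsurvError, RuntimeError):
    """The Newton iteration failed in a way that cannot be reported as a
    non-converged fit (non-finite likelihood, unrecoverable singular
    information)."""


class AuditViolationError(FedsurvError, RuntimeError):
    """A cross-node payload contained fields outside the aggregate schema."""
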