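"""Exception types shared across the package."""


class LinacbookError(Exception):
    """Base class for all package errors."""


class InvalidSlotError(LinacbookError):
    """A slot index outside the 1-based slot grid."""


class InfeasibleFrameError(LinacbookError):
    """A restricted time frame that contains no slot start."""


class BuildRefusedError(LinacbookError):
    """Model construction refused because the instance failed validation."""


class SolverUnavailableError(LinacbookError):
    """The MILP backend is missing or failed outside the model's control."""


class ExtractionError(LinacbookError):
    """Solution values too fractional or ill-formed to yield a schedule."""


class PreassignmentInfeasibleError(LinacbookError):
    """No feasible linac has residual capacity for a patient."""

    def __init__(self, patient_id: str, message: str | None = None):
        self.patient_id = patient_id
        super().__init__(message or f"no feasible linac with residual capacity for patient {patient_id!r}")


class ClusterSpecError(LinacbookError):
    """A cluster specification that is not a valid location-respecting partition."""


class ConfigError(LinacbookError):
    """An invalid generator or experiment configuration."""


class OracleTooLargeError(LinacbookError):
    """Exhaustive enumeration would exceed the search-space guard."""


class ParseError(LinacbookError):
    """A malformed instance/schedule/config file; names the offending field."""
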