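"""Exception hierarchy shared across the package."""


class OculogasError(Exception):
    """Base class for all package-specific errors."""


class DomainError(OculogasError, ValueError):
    """An input is outside the physical or numerical domain of an operation."""


class ConfigError(OculogasError, ValueError):
    """A configuration value violates its constraints."""


class InsufficientDataError(OculogasError, ValueError):
    """Too few observations to compute the requested statistic."""


class CohortSchemaError(OculogasError, ValueError):
    """A cohort file is missing required columns."""


class RowValidationError(OculogasError, ValueError):
    """One or more cohort rows failed validation.

    Carries ``failures``: a list of ``(row_number, field, message)`` tuples,
    with 1-based row numbers counted over data rows (header excluded).
    """

    def __init__(self, failures):
        self.failures = list(failures)
        lines = [f"row {r}, field '{f}': {m}" for r, f, m in self.failures]
        super().__init__(
            f"{len(self.failures)} cohort row(s) failed validation:\n" + "\n".join(lines)
        )
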