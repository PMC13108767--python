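"""Exception hierarchy for validation, estimation, and configuration failures."""

from __future__ import annotations


class PifcError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(PifcError):
    """An input table is missing a required column or has the wrong layout."""


class ValidationError(PifcError):
    """One or more rows violate a field invariant.

    Carries a list of (row_key, message) diagnostics so callers can report
    every offending row, not just the first.
    """

    def __init__(self, message: str, problems: list | None = None):
        self.problems = problems or []
        if self.problems:
            detail = "; ".join(str(p) for p in self.problems[:10])
            if len(self.problems) > 10:
                detail += f"; ... ({len(self.problems)} problems total)"
            message = f"{message}: {detail}"
        super().__init__(message)


class CompletenessError(PifcError):
    """A stratum grid is missing required cells (e.g., anchor years)."""

    def __init__(self, message: str, missing: list | None = None):
        self.missing = missing or []
        if self.missing:
            detail = "; ".join(str(m) for m in self.missing[:10])
            if len(self.missing) > 10:
                detail += f"; ... ({len(self.missing)} missing total)"
            message = f"{message}: {detail}"
        super().__init__(message)


class UniquenessError(PifcError):
    """Duplicate keys where a table requires one row per key."""


class SingularityError(PifcError):
    """A predictor has no usable variation on the estimation sample."""


class RankError(PifcError):
    """Fewer observations than parameters (or otherwise rank-deficient fit)."""


class ConfigurationError(PifcError):
    """A required coefficient, table, or setting is absent from the run configuration."""


class DomainError(PifcError, ValueError):
    """A numeric argument is outside its mathematical domain (e.g., prevalence
    passed as percent where a proportion is required)."""


class BootstrapError(PifcError):
    """Too many bootstrap replicates failed for the CI to be trustworthy."""
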