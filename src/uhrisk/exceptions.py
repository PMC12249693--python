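"""Exception hierarchy used across the package."""


class UhriskError(Exception):
    """Base class for package errors."""


class ConfigError(UhriskError, ValueError):
    """Invalid configuration (bad prevalence, non-positive scale, ...)."""


class CohortParseError(UhriskError, ValueError):
    """A cohort file could not be parsed or failed validation."""


class ConvergenceError(UhriskError, RuntimeError):
    """A model fit failed to converge (e.g. perfect separation)."""


class RankDeficiencyError(UhriskError, ValueError):
    """A design matrix is rank deficient; names the collinear columns."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            "design matrix is rank deficient; collinear columns: "
            + ", ".join(self.columns)
        )
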