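"""Exception hierarchy shared across wayfarer modules."""


class WayfarerError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(WayfarerError):
    """Invalid or inconsistent configuration."""


class FormatError(WayfarerError):
    """Malformed input file (missing columns, unparseable fields)."""


class DataError(WayfarerError):
    """Structurally valid input whose content violates a contract."""


class RankDeficiencyError(WayfarerError):
    """Design matrix is rank deficient after within-stratum centring."""

    def __init__(self, aliased: list[str]):
        self.aliased = list(aliased)
        super().__init__(
            "design matrix rank deficient after within-stratum centring; "
            f"aliased columns: {', '.join(self.aliased)}"
        )


class SeparationError(WayfarerError):
    """A covariate (combination) perfectly predicts cases; the conditional
    likelihood has no finite maximiser."""


class ConvergenceError(WayfarerError):
    """An iterative fit failed to converge within its iteration budget."""


class GradeError(WayfarerError):
    """Experienced percent grade outside the range covered by the
    oxygen-consumption regressions."""
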