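"""Exception hierarchy for cinsynergy."""


class CinSynergyError(Exception):
    """Base class for all package errors."""


class ConfigError(CinSynergyError):
    """Invalid simulation or pipeline configuration."""


class DesignError(CinSynergyError):
    """Screen design is incomplete (e.g. a cell line without a vehicle control)."""


class GridError(CinSynergyError):
    """Time grids are incompatible for the requested operation."""


class InsufficientDataError(CinSynergyError):
    """Too few observations for the requested estimate."""


class NormalizationError(CinSynergyError):
    """Control-relative normalization cannot be computed."""


class AnalysisError(CinSynergyError):
    """A statistical comparison is undefined for the given inputs."""


class DegenerateTableError(CinSynergyError):
    """A contingency table has a zero marginal."""


class ScreenValidationError(CinSynergyError):
    """A screen table failed schema or value validation."""

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__(
            "screen table validation failed:\n  " + "\n  ".join(self.problems)
        )
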