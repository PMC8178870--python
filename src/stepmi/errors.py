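"""Exception types raised across the package."""


class StepmiError(Exception):
    """Base class for all package-specific errors."""


class MalformedInputError(StepmiError, ValueError):
    """Input data violates a structural requirement (length, duplicates, range)."""


class SchemaError(StepmiError, ValueError):
    """A table is missing required columns or contains invalid codes."""


class ParameterError(StepmiError, ValueError):
    """A configuration parameter is out of its allowed range."""


class RankDeficiencyError(StepmiError, ValueError):
    """Design matrix is rank deficient.

    Attributes
    ----------
    columns : list
        Names/indices of the columns implicated in the deficiency.
    """

    def __init__(self, message, columns=None):
        super().__init__(message)
        self.columns = list(columns) if columns is not None else []


class ConvergenceError(StepmiError, RuntimeError):
    """An iterative fit failed to converge.

    Attributes
    ----------
    last_objective : float or None
        Objective value at the final iterate, for diagnostics.
    """

    def __init__(self, message, last_objective=None):
        super().__init__(message)
        self.last_objective = last_objective


class ScenarioStageError(StepmiError, RuntimeError):
    """A pipeline stage failed inside a scenario run; carries the stage name."""

    def __init__(self, stage, original):
        super().__init__(f"scenario stage '{stage}' failed: {original}")
        self.stage = stage
        self.original = original
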