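"""Exception types shared across the package."""


class InputError(ValueError):
    """Invalid input data (bad geometry, missing columns, out-of-window points)."""


class ConfigError(ValueError):
    """Invalid or infeasible run configuration."""


class InsufficientDataError(InputError):
    """Too few observations to compute a reportable statistic."""


class SaturationError(RuntimeError):
    """Sequential placement exhausted its attempt budget before reaching the
    target cell count.

    Attributes
    ----------
    achieved : int
        Number of cells successfully placed before giving up.
    target : int
        Requested cell count.
    """

    def __init__(self, achieved: int, target: int):
        self.achieved = achieved
        self.target = target
        super().__init__(
            f"placement saturated at {achieved} of {target} cells; "
            "lower the target density or enlarge the window"
        )
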