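"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A food-web configuration, diet matrix, or run setup is invalid."""


class ForcingDataError(ValueError):
    """A forcing series is malformed (ragged years, non-finite values...)."""


class StateCorruptionError(RuntimeError):
    """An ecosystem state contains negative or otherwise impossible values."""


class SimulationDivergedError(RuntimeError):
    """The simulation produced non-finite state.

    Carries the simulated year and the first offending group so the
    failure can be traced back to a parameterization problem.
    """

    def __init__(self, year: int, group: str):
        self.year = year
        self.group = group
        super().__init__(
            f"simulation diverged (non-finite state) at year {year}, group {group!r}"
        )


class CompletenessError(ValueError):
    """An evaluation was attempted on an incomplete set of runs/summaries."""
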