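"""Exception hierarchy for the waterreach pipeline."""


class WaterReachError(Exception):
    """Base class for all pipeline errors."""


class ConfigError(WaterReachError):
    """Invalid configuration; the message names the offending field."""


class TrialTimingError(WaterReachError):
    """Inconsistent trial event times (e.g. touch registered before reward)."""


class TruncationError(WaterReachError):
    """Stream too short to cover the analysis window."""


class GeometryError(WaterReachError):
    """Spout/platform geometry could not be resolved from the pose tracks."""


class WindowError(WaterReachError):
    """Requested analysis window not covered by the data."""


class RegistrationError(WaterReachError):
    """Atlas registration failure (too few or degenerate landmarks)."""


class ImagingError(WaterReachError):
    """Widefield stack processing failure."""


class StageError(WaterReachError):
    """A pipeline stage failed; carries the stage name and trial index."""

    def __init__(self, stage: str, message: str, trial_index: int | None = None):
        self.stage = stage
        self.trial_index = trial_index
        where = f"stage '{stage}'" + (
            f", trial {trial_index}" if trial_index is not None else ""
        )
        super().__init__(f"{where}: {message}")
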