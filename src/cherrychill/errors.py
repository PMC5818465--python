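"""Exception hierarchy shared across the package."""


class CherryChillError(Exception):
    """Base class for all package errors."""


class InputError(CherryChillError, ValueError):
    """Invalid user-supplied data (non-finite temperatures, bad weights...)."""


class WindowError(CherryChillError, ValueError):
    """An accumulation or correlation window is empty or ill-ordered."""


class ThresholdError(CherryChillError, ValueError):
    """A color ThresholdSpec violates 0 <= min <= max <= 255."""


class GeometryError(CherryChillError, ValueError):
    """A frame or transect does not fit inside the image."""


class DegenerateDataError(CherryChillError, ValueError):
    """A statistic is undefined on the given data (zero variance etc.)."""


class StageError(CherryChillError, RuntimeError):
    """A pipeline stage failed; carries the stage name for fail-fast reports."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
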