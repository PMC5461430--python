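"""Exception hierarchy shared across the pipeline stages."""


class PhenovolError(Exception):
    """Base class for all package errors."""


class ConfigError(PhenovolError):
    """A configuration value is missing, inconsistent or unattainable."""


class FrameOverflowError(ConfigError):
    """The rendered plant does not fit in the image frame.

    Carries the minimum frame size (width, height in pixels) that would
    contain the projection at the configured pixel scale.
    """

    def __init__(self, required_width: int, required_height: int):
        self.required_width = int(required_width)
        self.required_height = int(required_height)
        super().__init__(
            f"plant silhouette exceeds the image frame; requires at least "
            f"{self.required_width} x {self.required_height} pixels"
        )


class InvalidInputError(PhenovolError):
    """An operation received data violating its preconditions."""


class SingularFitError(PhenovolError):
    """A regression design matrix is singular (e.g. zero volume variance)."""


class CurveQualityError(PhenovolError):
    """A standard curve's points are unusable (e.g. non-monotone response)."""


class UnsupportedDesignError(PhenovolError):
    """The factorial design is not supported (e.g. unbalanced two-way ANOVA)."""


class StageError(PhenovolError):
    """A pipeline stage failed; names the stage and the offending input."""

    def __init__(self, stage: str, detail: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {detail}")
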