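"""Exception types shared across the pipeline stages."""


class ParameterError(ValueError):
    """An input parameter violates its documented domain."""


class RegistrationError(RuntimeError):
    """Registration cannot proceed (e.g. blank frame, shape mismatch)."""


class DetectionError(RuntimeError):
    """Noise calibration or detection cannot proceed."""


class EmptyResultError(RuntimeError):
    """A stage produced no output; downstream stages must refuse to run."""

    def __init__(self, stage: str, message: str = ""):
        self.stage = stage
        super().__init__(f"[{stage}] empty result: {message}")
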