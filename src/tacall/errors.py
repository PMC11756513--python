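"""Exception hierarchy shared across the package."""


class TacallError(Exception):
    """Base class for all package-specific errors."""


class CurveIOError(TacallError):
    """Malformed trace, label, or call file; message names the offending reaction."""


class AlignmentError(TacallError):
    """Calls, labels, and traces do not align by reaction_id."""


class ModelError(TacallError):
    """Model cannot be trained or applied under the given inputs."""


class PipelineError(TacallError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
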