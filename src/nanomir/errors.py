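"""Exception hierarchy for the nanomir pipeline.

Every stage raises a subclass of :class:`NanomirError` so callers (and the
CLI) can distinguish pipeline failures from programming errors.
"""


class NanomirError(Exception):
    """Base class for all nanomir errors."""


class RCCFormatError(NanomirError):
    """The file is not a recognisable RCC lane file (e.g. no Code_Summary)."""


class RCCParseError(NanomirError):
    """A Code_Summary row could not be parsed (bad count, wrong arity)."""


class ValidationError(NanomirError):
    """A domain invariant is violated (duplicate probes, bad evidence tag...)."""


class IncompatibleLanesError(NanomirError):
    """Lanes with differing probe sets cannot be assembled into one matrix."""


class DesignError(NanomirError):
    """The sample design does not cover the lanes (or references unknown ones)."""


class InsufficientControlsError(NanomirError):
    """Too few control probes for the requested computation."""


class ConfigurationError(NanomirError):
    """A required configuration element (reference gene, path...) is missing."""


class QCError(NanomirError):
    """A lane fails a fatal quality-control precondition."""


class PipelineStageError(NanomirError):
    """Wraps any error raised inside a named pipeline stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
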