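"""Typed failures raised by the pipeline.

Every anticipated bad input maps to one of these classes so callers (and the
CLI) can distinguish a malformed recording from a programming error.
"""


class PostureKitError(Exception):
    """Base class for all labelled pipeline failures."""


class ProtocolError(PostureKitError):
    """A simulation protocol is inconsistent (unknown label, no standing segment, ...)."""


class CalibrationError(PostureKitError):
    """A standing calibration interval is unusable (outside the recording, degenerate)."""


class MissingSensorError(PostureKitError):
    """A required sensor position is absent from the recording."""


class FormatError(PostureKitError):
    """A file does not conform to the tabular recording/annotation schema."""


class ModelError(PostureKitError):
    """A classifier is misconfigured or applied to mismatched features."""
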