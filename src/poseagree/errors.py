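"""Exception hierarchy for poseagree."""


class PoseagreeError(Exception):
    """Base class for all poseagree errors."""


class ParseError(PoseagreeError):
    """A record in an input file could not be parsed."""


class LayoutError(PoseagreeError):
    """A frame's landmark count or layout mapping is inconsistent."""


class AmbiguityError(PoseagreeError):
    """Duplicate (video, frame, joint) rows make the input ambiguous."""


class ConfigurationError(PoseagreeError):
    """A triplet landmark cannot be resolved in the stream's layout."""


class DegenerateGeometryError(PoseagreeError):
    """A zero-length ray makes the interior angle undefined."""


class ParameterError(PoseagreeError):
    """An invalid window size or other numeric parameter."""


class UnimputableError(PoseagreeError):
    """A series is entirely missing and cannot be imputed."""


class PairingError(PoseagreeError):
    """Candidate and reference series cannot be frame-aligned."""


class InsufficientDataError(PoseagreeError):
    """Too few pairs for the requested statistic."""


class UndefinedStatisticError(PoseagreeError):
    """Zero variance (or similar degeneracy) makes a statistic undefined."""


class ValidationError(PoseagreeError):
    """A simulation spec violates its invariants."""
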