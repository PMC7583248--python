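"""Typed exceptions raised across the pipeline.

Every reader/validator raises one of these instead of silently truncating
or coercing malformed input.
"""


class LarfamError(Exception):
    """Base class for all package errors."""


class ValidationError(LarfamError):
    """A value or configuration violates a documented invariant."""


class AlphabetError(ValidationError):
    """A sequence contains a character outside the 20-letter amino-acid alphabet."""


class DuplicateIdError(ValidationError):
    """Two records in one collection share an id."""


class FormatError(LarfamError):
    """A file does not conform to its declared external format."""


class AnchorConfigError(ValidationError):
    """Anchor configuration inconsistent with the reference sequence."""


class AlignmentError(LarfamError):
    """Alignment preconditions violated (e.g. empty sequence)."""


class GroupingError(LarfamError):
    """Clustering preconditions violated or unknown group referenced."""


class AssociationError(LarfamError):
    """Gene-context association preconditions violated."""


class SignatureError(LarfamError):
    """Signature profiling/classification preconditions violated."""


class FitError(LarfamError):
    """Kinetics model fitting failed or preconditions violated."""

    def __init__(self, message, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


class SimulationError(ValidationError):
    """Synthetic-data configuration is internally inconsistent."""


class PipelineError(LarfamError):
    """A pipeline stage aborted; carries the stage name and an error code."""

    def __init__(self, stage, code, message):
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage = stage
        self.code = code
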