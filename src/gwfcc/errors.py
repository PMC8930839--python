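"""Error classes shared across the pipeline stages."""


class GwfccError(Exception):
    """Base class for all package errors."""


class ConfigError(GwfccError, ValueError):
    """Invalid configuration value or unknown configuration key."""


class ShapeError(GwfccError, ValueError):
    """Array shapes or grids do not agree."""


class StateError(GwfccError, RuntimeError):
    """Operation called on an object in the wrong state (e.g. unfiltered signals)."""


class AlignmentError(GwfccError, ValueError):
    """Subject sets or orderings do not line up between two containers."""


class InsufficientDataError(GwfccError, ValueError):
    """Too few subjects/observations for the requested statistic."""


class EmptyMaskError(GwfccError, ValueError):
    """A tissue mask contains no voxels."""


class DegenerateInputError(GwfccError, ValueError):
    """Input is degenerate (e.g. zero whole-brain mean, single-class labels)."""
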