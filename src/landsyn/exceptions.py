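"""Exception hierarchy for the landing-synergy pipeline."""


class LandsynError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(LandsynError):
    """Invalid parameter combination (e.g. cutoff above Nyquist)."""


class DataError(LandsynError):
    """Malformed input data (non-finite samples, wrong shapes)."""


class SegmentationError(LandsynError):
    """A landing could not be segmented (no touchdown, no stance end)."""


class NormalizationError(LandsynError):
    """Amplitude normalization impossible (all-zero reference muscle)."""


class DegenerateInputError(LandsynError):
    """Input with no usable structure (e.g. all-zero EMG matrix)."""
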