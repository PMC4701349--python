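"""Exception hierarchy for the reader pipeline.

Every stage raises a distinct subclass so the pipeline (and the CLI exit
codes) can distinguish "could not locate the test" from "wrong number of
strips" from plain bad input.
"""


class LFAError(Exception):
    """Base class for all reader errors."""


class ConfigurationError(LFAError):
    """Invalid panel / generator / model configuration."""


class GenerationError(LFAError):
    """Synthetic rendering failed (e.g. pose pushes the card off-frame)."""


class TemplateError(LFAError):
    """Template image unusable (too few keypoints, bad quad)."""


class RegistrationError(LFAError):
    """The strip region could not be located in the captured image."""


class SegmentationError(LFAError):
    """Strip-label segmentation disagrees with the declared panel."""


class HistogramError(LFAError):
    """Lateral-histogram extraction or preprocessing failed."""


class DataError(LFAError):
    """Training data unusable (missing classes, degenerate bins)."""
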