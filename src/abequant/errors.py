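"""Exception hierarchy for abequant.

Failures are loud by design: empty ROIs, degenerate inputs and broken
dataset integrity raise instead of propagating silent zeros into the
feature table or the statistics downstream.
"""


class AbequantError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(AbequantError, ValueError):
    """Invalid phantom or training configuration (non-finite, negative SD...)."""


class RenderingError(AbequantError, ValueError):
    """Slice geometry cannot be realized (e.g. grid too small for the ROIs)."""


class IntegrityError(AbequantError, ValueError):
    """Dataset files/tables disagree (missing masks, subject-id mismatch...)."""


class EmptyRegionError(AbequantError, ValueError):
    """A requested ROI code has no pixels in the mask."""


class SelectionError(AbequantError, ValueError):
    """No slice in a stack carries the ROIs needed for analysis."""


class DegenerateInputError(AbequantError, ValueError):
    """Input admits no meaningful answer (single-class labels, constant image...)."""


class UndefinedMetricError(AbequantError, ValueError):
    """A metric's denominator is zero; surfaced explicitly, never as 0."""


class CollinearityError(AbequantError, ValueError):
    """Design matrix is rank deficient."""
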