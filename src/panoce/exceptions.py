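"""Exception hierarchy for the panoce pipeline."""


class PanoceError(Exception):
    """Base class for all panoce-specific errors."""


class ValidationError(PanoceError, ValueError):
    """Invalid input data or inconsistent specification."""


class AliasingError(PanoceError):
    """Interframe phase would wrap by more than pi per axial pixel.

    Raised by the frame-stream simulator when the implied per-step phase
    gradient in the softest layer exceeds the Nyquist limit of the
    phase-difference method.  The fix is to reduce the per-step surface
    displacement (smaller compression increments).
    """


class StressWindowError(PanoceError):
    """The cumulative stress never enters (or jumps across) the
    standardization window."""


class DecompressionError(PanoceError):
    """Cumulative reference-layer strain decreased between increments."""


class EmptyReferenceError(PanoceError):
    """No valid reference-layer pixels available to estimate stress."""
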