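"""Exception hierarchy for the spineqct pipeline."""


class SpineQCTError(Exception):
    """Base class for all spineqct errors."""


class ValidationError(SpineQCTError, ValueError):
    """A specification or configuration field violates its invariants.

    The message always names the offending field.
    """


class CalibrationError(SpineQCTError, ValueError):
    """Degenerate phantom input: too few rods, identical attenuations,
    or a rod ROI emptied by erosion."""


class RegistrationError(SpineQCTError, RuntimeError):
    """Registration preconditions violated (no overlap, too few voxels)."""


class MeasurementError(SpineQCTError, ValueError):
    """An image measurement cannot be made (empty mask, empty region)."""


class ReportError(SpineQCTError, ValueError):
    """The cohort table is malformed (missing sessions, bad schema)."""
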