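"""Exception hierarchy for ribotrace."""


class RibotraceError(Exception):
    """Base class for all ribotrace errors."""


class TraceFormatError(RibotraceError):
    """A trace file or in-memory trace violates the trace contract."""


class SampleSheetError(TraceFormatError):
    """A sample sheet is malformed (missing columns, bad roles, duplicate ids)."""


class CalibrationError(RibotraceError):
    """Ladder peak detection or size-calibration fitting failed."""


class FitError(RibotraceError):
    """A kinetic or regression fit cannot be performed on the given data."""
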