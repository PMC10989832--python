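"""Exception hierarchy shared across the pipeline."""


class RhizotraceError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigError(RhizotraceError, ValueError):
    """A simulation or run configuration violates its invariants."""


class ParseError(RhizotraceError, ValueError):
    """An on-disk table or tree could not be validated."""


class DegenerateInputError(RhizotraceError, ValueError):
    """Input is structurally valid but carries no usable signal
    (e.g. an all-zero root mask, a single-taxon metacommunity)."""


class InsufficientDataError(RhizotraceError, ValueError):
    """Fewer observations than the operation requires."""


class DegenerateCalibrationError(RhizotraceError, ValueError):
    """Calibration points conflict (same gray, different concentration)."""
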