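"""Exception hierarchy shared across the package."""


class MicrostabError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MicrostabError):
    """Malformed input file (bad cell value, duplicate id, missing column)."""


class DesignError(MicrostabError):
    """Invalid consortium design (wrong pool size, unknown member)."""


class DomainError(MicrostabError):
    """Operation called outside its mathematical domain."""


class ScaleRangeError(DomainError):
    """Requested wavelet scale outside the admissible range for the series."""


class AlignmentError(DomainError):
    """Per-probe results computed on mismatched scale grids."""


class DegenerateStabilityError(DomainError):
    """Overall wavelet variance is zero: stability 1/V_t is infinite."""


class DegenerateCorrelationError(DomainError):
    """Pearson correlation undefined (zero-variance input)."""
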