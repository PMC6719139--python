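"""Exception hierarchy shared by all vcgbeat modules."""


class VcgError(Exception):
    """Base class for all vcgbeat errors."""


class FormatError(VcgError):
    """A file or column-mapping did not match the expected CSV dialect."""


class InsufficientDataError(VcgError):
    """Too few samples (or too short a recording) for the requested operation."""


class ParameterError(VcgError):
    """A parameter is outside its valid range (e.g. cutoff above Nyquist)."""


class UndefinedStatisticError(VcgError):
    """A statistic has an empty or degenerate denominator (e.g. TP+FN = 0)."""
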