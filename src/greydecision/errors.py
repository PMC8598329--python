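"""Exception hierarchy.

All package errors derive from :class:`GreyDecisionError`; the concrete
classes also subclass :class:`ValueError` so that generic input-validation
handling keeps working for callers that do not import this module.
"""


class GreyDecisionError(Exception):
    """Base class for all errors raised by greydecision."""


class InputError(GreyDecisionError, ValueError):
    """An argument is outside its documented domain."""


class DimensionError(GreyDecisionError, ValueError):
    """Two series or matrices that must align do not."""


class NormalizationError(GreyDecisionError, ValueError):
    """A normalization step hit a zero divisor; names the offending object."""


class PanelParseError(GreyDecisionError, ValueError):
    """A long-format panel CSV is malformed; carries a line number when known."""


class IncompleteGridError(GreyDecisionError, ValueError):
    """A factor x country grid has missing pairs; lists them."""


class DegenerateDistanceError(GreyDecisionError, ZeroDivisionError):
    """Both distance sums are zero, so the assessment degree is undefined."""
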