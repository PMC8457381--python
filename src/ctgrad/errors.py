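"""Exception hierarchy.

All package errors derive from :class:`CtgradError` so callers can catch
everything with one clause; the subclasses distinguish bad numeric inputs
(``DomainError``), malformed records (``ValidationError``), degenerate
geometry (``GeometryError``), signals that cannot be analysed
(``AnalysisError``), failed model fits (``FitError``) and unreadable files
(``ParseError``).
"""


class CtgradError(Exception):
    """Base class for all errors raised by ctgrad."""


class DomainError(CtgradError, ValueError):
    """A numeric argument is outside the physical domain of an operation."""


class ValidationError(CtgradError, ValueError):
    """A record or data structure violates its invariants."""


class GeometryError(CtgradError):
    """A contour or geometry object is degenerate or ill-formed."""


class AnalysisError(CtgradError):
    """A signal does not contain the feature the analysis requires."""


class FitError(CtgradError):
    """A model fit cannot be set up (under-determined or degenerate design)."""


class ParseError(CtgradError):
    """A file does not conform to its documented schema."""
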