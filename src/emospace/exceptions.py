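"""Exception hierarchy.

Validation problems (bad files, out-of-range values, mismatched labels)
raise subclasses of :class:`EmospaceError` so callers — in particular the
command-line interface — can distinguish user-input errors from bugs.
"""


class EmospaceError(Exception):
    """Base class for all validation and input errors raised by emospace."""


class FormatError(EmospaceError):
    """A file could not be parsed; the message names the offending row."""


class RangeError(EmospaceError):
    """A rating or parameter lies outside its documented range."""


class DuplicateEntryError(EmospaceError):
    """The same (participant, emotion, aspect) triple appears twice."""


class AlignmentError(EmospaceError):
    """Two labelled objects do not share a common label set/order."""


class DimensionalityError(EmospaceError):
    """An operation defined for a fixed number of aspects/dimensions got another."""


class DegenerateInputError(EmospaceError):
    """Input is structurally valid but degenerate (e.g. all-zero dissimilarities)."""


class UndefinedCoefficientError(EmospaceError):
    """A correlation coefficient is undefined (zero variance); names the variable."""


class FeasibilityError(EmospaceError):
    """A simulation specification cannot be realised (e.g. no mass in [0, 100])."""


class SummarizationError(EmospaceError):
    """A summary cell has no observations to aggregate."""
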