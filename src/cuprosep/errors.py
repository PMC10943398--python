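"""Exception hierarchy.

``ValueError`` (or :class:`ArgumentError`) signals a caller mistake — an
argument outside its documented domain.  :class:`DataError` signals data
that is structurally valid Python but scientifically unusable (a batch
with one sample, a single-class label vector, disjoint gene sets).
"""


class ArgumentError(ValueError):
    """An argument lies outside its documented domain."""


class DataError(ValueError):
    """Input data cannot support the requested computation."""


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""
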