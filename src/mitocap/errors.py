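"""Exception hierarchy shared across the pipeline stages."""


class MitocapError(Exception):
    """Base class for all mitocap errors."""


class InvalidParameterError(MitocapError, ValueError):
    """A numeric or structural parameter is outside its allowed range."""


class EmptyInputError(MitocapError, ValueError):
    """An operation that needs at least one record received none."""


class UndefinedValueError(MitocapError, ValueError):
    """The requested quantity is undefined for this input (e.g. 0/0)."""


class ConsistencyError(MitocapError, ValueError):
    """Two inputs that must agree (ids, references, lengths) do not."""


class CoordinateError(MitocapError, ValueError):
    """A position falls outside the reference coordinate space."""


class MalformedAlignmentError(MitocapError, ValueError):
    """An alignment record cannot be interpreted (CIGAR/sequence mismatch)."""
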