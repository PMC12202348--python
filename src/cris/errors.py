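"""Exception hierarchy for the CRIS toolkit."""


class CrisError(Exception):
    """Base class for all toolkit errors."""


class ConfigParseError(CrisError):
    """A structured-text document (YAML/JSON/BibTeX) could not be parsed."""


class MatrixValidationError(CrisError):
    """A foundational search matrix violates an invariant."""


class CellReferenceError(CrisError):
    """A reference to a (category, discipline, perspective) cell that does not exist."""


class UnsupportedShapeError(CrisError):
    """An operation defined only for the 2-discipline / 2-perspective case."""


class SpecError(CrisError):
    """A synthetic-corpus specification cannot be realized."""


class StateError(CrisError):
    """An operation applied to an entry in the wrong state."""


class InputError(CrisError):
    """Invalid caller-supplied values (empty vote map, zero denominator, ...)."""
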