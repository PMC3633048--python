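"""Exception hierarchy shared across the package."""


class OntoevalError(Exception):
    """Base class for all package-specific errors."""


class OntologyStructureError(OntoevalError):
    """The ontology graph violates a structural requirement (cycle,
    dangling parent reference, missing root)."""


class TermLookupError(OntoevalError, KeyError):
    """A term id is unknown or obsolete in the ontology."""


class ValidationError(OntoevalError, ValueError):
    """An input value violates a contract (score range, term cap, ...)."""


class ParseError(OntoevalError):
    """A flat file could not be parsed; carries line context."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number
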