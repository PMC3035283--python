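"""Exception hierarchy for termspec.

All library errors derive from :class:`TermspecError` so callers can catch
one base class. The CLI maps ontology-validation errors to exit code 1 and
file/schema errors to exit code 2.
"""


class TermspecError(Exception):
    """Base class for all termspec errors."""


class OntologyValidationError(TermspecError):
    """Base for structural problems detected while loading an ontology."""


class CyclicOntologyError(OntologyValidationError):
    """The term graph contains a directed cycle.

    The message names at least one term on the cycle.
    """


class DanglingEdgeError(OntologyValidationError):
    """A term references a parent that is not defined in the ontology."""


class RootResolutionError(OntologyValidationError):
    """Zero or more than one root term after namespace/edge filtering."""


class AmbiguousNamespaceError(OntologyValidationError):
    """Multiple namespaces present but no namespace filter was given."""


class UnknownTermError(TermspecError, KeyError):
    """A term identifier was not found in the ontology."""

    def __str__(self) -> str:  # KeyError quotes its args; keep plain text
        return Exception.__str__(self)


class SchemaError(TermspecError):
    """An annotation file does not have the expected columns."""


class EmptyAnnotationError(TermspecError):
    """No annotation rows survived parsing and filtering."""


class BoundsError(TermspecError, ValueError):
    """A numeric argument is outside its documented domain."""


class SpecError(TermspecError, ValueError):
    """A synthetic-data specification is infeasible."""
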