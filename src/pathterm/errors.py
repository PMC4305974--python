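"""Exception hierarchy shared by all pathterm modules."""

from __future__ import annotations


class PathtermError(Exception):
    """Base class for all pathterm errors."""


class MissingConceptError(PathtermError):
    """A concept referenced by an operation is not registered in the graph."""


class CycleError(PathtermError):
    """Adding an edge would create a cycle in an acyclic relationship.

    Carries the offending path (concept designations, child to ancestor).
    """

    def __init__(self, path: list[str]):
        self.path = list(path)
        super().__init__("cycle via: " + " -> ".join(self.path))


class RoleConstraintError(PathtermError):
    """A concept violates the permissible set of the role it was placed in."""

    def __init__(self, role: str, designation: str, message: str | None = None):
        self.role = role
        self.designation = designation
        super().__init__(
            message or f"concept {designation!r} is not permissible in role {role!r}"
        )


class ExpressionValidationError(PathtermError):
    """Aggregated role/constraint violations raised by the composer."""

    def __init__(self, errors: list[PathtermError]):
        self.errors = list(errors)
        super().__init__("; ".join(str(e) for e in self.errors))


class GraphMismatchError(PathtermError):
    """Two expressions from different ontology graphs were compared."""


class NameParseError(PathtermError):
    """A precoordinated term name could not be parsed."""


class NotFoundError(PathtermError):
    """A requested element is absent from the registry."""


class CoverageUndefinedError(PathtermError):
    """SNOMED coverage was requested for an empty concept collection."""


class ConfigurationError(PathtermError):
    """A recipe or profile references a concept unknown to the ontology."""


class DialectError(PathtermError):
    """A registry file does not conform to the declared dialect."""


class SerializationError(PathtermError):
    """A serialized expression could not be parsed back."""
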