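"""Exception hierarchy shared across the toolkit."""


class MedkgError(Exception):
    """Base class for all toolkit errors."""


class SchemaViolationError(MedkgError):
    """A relation references an entity that is not in the graph."""


class RelationTypeError(MedkgError, TypeError):
    """Subject/object concept class does not match the relation schema."""


class CorpusFormatError(MedkgError, ValueError):
    """Malformed corpus file or violated corpus invariant."""


class ParseError(MedkgError):
    """Dependency parse is unusable (disconnected, cyclic, multi-rooted)."""


class ConfigurationError(MedkgError, ValueError):
    """Invalid or insufficient configuration for an operation."""


class ProvenanceError(MedkgError):
    """A relation's provenance points outside the corpus."""


class FeatureError(MedkgError):
    """Chain featurization failed (e.g. a relation without provenance)."""


class TrainingError(MedkgError):
    """Classifier training is impossible (e.g. single-class data)."""


class ModelCompatibilityError(MedkgError):
    """A fitted pruner is applied to chains it cannot featurize."""


class AuditError(MedkgError):
    """A generated bundle violates one of its declared invariants."""
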