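"""Exception hierarchy for claimrules.

Validation findings on rules are data (see :mod:`claimrules.model`), not
exceptions; exceptions are reserved for malformed inputs, impossible
requests and programming errors.
"""


class ClaimRulesError(Exception):
    """Base class for all claimrules errors."""


class OntologyFormatError(ClaimRulesError):
    """An ontology file could not be parsed."""


class OntologyConsistencyError(ClaimRulesError):
    """The ontology violates its own invariants (e.g. asymmetric disjointness)."""


class UnknownPropertyError(ClaimRulesError):
    """A rule references a condition property the ontology does not define."""


class RuleStructureError(ClaimRulesError):
    """A rule graph is not a tree (cycle or disconnected component)."""


class RuleFormatError(ClaimRulesError):
    """A rule file could not be parsed."""


class InvalidBoundError(ClaimRulesError):
    """An upper-bound condition carries a non-positive limit."""


class IncompleteTemporalError(ClaimRulesError):
    """A time amount appears without a time unit, or vice versa."""


class UnknownTimeUnitError(ClaimRulesError):
    """A time unit outside day/week/month/year."""


class BindingError(ClaimRulesError):
    """A rule condition has no entry in the field map."""


class IncompleteRuleError(ClaimRulesError):
    """A normalized rule cannot be compiled into a pipeline (e.g. a service
    limitation without a threshold)."""


class ProvenanceError(ClaimRulesError):
    """Rule matching requires source provenance that is missing."""


class DegenerateEmbeddingError(ClaimRulesError):
    """An embedder returned a zero-norm vector."""


class InsufficientDataError(ClaimRulesError):
    """Fewer rules than a pairwise summary needs."""


class SchemaError(ClaimRulesError):
    """A claim record violates the claims schema."""


class ParameterError(ClaimRulesError):
    """An engine parameter is out of range (e.g. non-positive window)."""


class ContextSizeError(ClaimRulesError):
    """The brute-force oracle refuses contexts beyond its size guard."""


class ConsistencyError(ClaimRulesError):
    """Cross-references disagree (flag vs rule, flag vs claims database)."""


class GenerationError(ClaimRulesError):
    """The synthetic generator could not construct a clean background."""


class PlantingError(ClaimRulesError):
    """A requested violation cannot be planted."""
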