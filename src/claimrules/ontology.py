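"""Condition vocabulary ("ontology-lite") for rule knowledge graphs.

Each rule condition refers to a named property such as ``hasMaxUnits`` or
``hasApplicableService``.  The ontology declares, per property, the kind of
values it takes, how many conditions of that property a single rule may
carry, whether the property expresses an upper or lower bound, which
properties it is disjoint with (a procedure code cannot be both applicable
and excluded in the same rule), and which claim field it naturally reads.

A built-in vocabulary covering the standard dental-policy properties ships
with the package so nothing needs to be downloaded; ontologies may also be
loaded from a JSON file or from RDF (Turtle / N-Triples).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import rdflib
from rdflib.namespace import RDF, RDFS

from .errors import OntologyConsistencyError, OntologyFormatError

__all__ = [
    "ConditionDef",
    "Ontology",
    "load_ontology",
    "builtin_ontology",
    "CR",
    "VALUE_KINDS",
    "CANONICAL_ALIASES",
]

#: RDF namespace used for serialized rules and ontologies.
CR = rdflib.Namespace("https://w3id.org/claimrules#")

VALUE_KINDS = frozenset(
    {"numeric", "duration-amount", "duration-unit", "code-set", "categorical"}
)

#: Singular/plural drift seen in rule files is canonicalized to one surface form.
CANONICAL_ALIASES: Mapping[str, str] = {
    "hasMinUnit": "hasMinUnits",
    "hasMaxUnit": "hasMaxUnits",
    "hasApplicableServices": "hasApplicableService",
    "hasExcludedServices": "hasExcludedService",
}


def canonical_name(name: str) -> str:
    """Map vocabulary aliases (e.g. ``hasMinUnit``) to the canonical property name."""
    return CANONICAL_ALIASES.get(name, name)


@dataclass(frozen=True)
class ConditionDef:
    """Declaration of one condition property.

    Parameters
    ----------
    name
        Canonical property identifier, e.g. ``hasMaxUnits``.
    value_kind
        One of ``numeric``, ``duration-amount``, ``duration-unit``,
        ``code-set``, ``categorical``.
    max_cardinality
        Maximum number of conditions of this property a rule may carry;
        ``math.inf`` for unbounded.
    bound_polarity
        ``upper`` / ``lower`` for threshold-like numeric properties,
        ``none`` otherwise.
    disjoint_with
        Names of properties whose value sets must not overlap with this
        one inside a single rule.
    field_hint
        Claim field the property naturally reads, or ``None``.
    """

    name: str
    value_kind: str
    max_cardinality: float = 1
    bound_polarity: str = "none"
    disjoint_with: frozenset[str] = field(default_factory=frozenset)
    field_hint: str | None = None

    def __post_init__(self) -> None:
        if self.value_kind not in VALUE_KINDS:
            raise OntologyFormatError(
                f"{self.name}: unknown value kind {self.value_kind!r}"
            )
        if self.bound_polarity not in {"upper", "lower", "none"}:
            raise OntologyFormatError(
                f"{self.name}: unknown bound polarity {self.bound_polarity!r}"
            )
        if not (self.max_cardinality == math.inf or self.max_cardinality >= 1):
            raise OntologyFormatError(
                f"{self.name}: max_cardinality must be >= 1 or unbounded"
            )
        if self.value_kind in {"numeric", "duration-amount"} and self.max_cardinality != 1:
            raise OntologyConsistencyError(
                f"{self.name}: {self.value_kind} conditions must have cardinality 1"
            )

    @property
    def is_numeric(self) -> bool:
        """Whether single values of this property compare on the number line."""
        return self.value_kind in {"numeric", "duration-amount"}


class Ontology:
    """A consistent collection of :class:`ConditionDef`, keyed by canonical name."""

    def __init__(self, defs: Iterable[ConditionDef]):
        self._defs: dict[str, ConditionDef] = {}
        for d in defs:
            if d.name in self._defs:
                raise OntologyConsistencyError(f"duplicate condition def {d.name!r}")
            self._defs[d.name] = d
        self._check_disjointness_symmetry()

    def _check_disjointness_symmetry(self) -> None:
        for d in self._defs.values():
            for other in d.disjoint_with:
                peer = self._defs.get(other)
                if peer is None:
                    raise OntologyConsistencyError(
                        f"{d.name} declared disjoint with unknown property {other!r}"
                    )
                if d.name not in peer.disjoint_with:
                    raise OntologyConsistencyError(
                        f"disjointness is not symmetric: {d.name} -> {other} "
                        f"but not {other} -> {d.name}"
                    )

    def __contains__(self, name: str) -> bool:
        return canonical_name(name) in self._defs

    def __getitem__(self, name: str) -> ConditionDef:
        return self._defs[canonical_name(name)]

    def __iter__(self) -> Iterator[ConditionDef]:
        return iter(self._defs.values())

    def __len__(self) -> int:
        return len(self._defs)

    def get(self, name: str) -> ConditionDef | None:
        return self._defs.get(canonical_name(name))

    @property
    def names(self) -> list[str]:
        return sorted(self._defs)


def _sym(pairs: Iterable[tuple[str, str]]) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    for a, b in pairs:
        out.setdefault(a, set()).add(b)
        out.setdefault(b, set()).add(a)
    return out


def builtin_ontology() -> Ontology:
    """The bundled vocabulary of dental-policy condition properties."""
    disjoint = _sym([("hasApplicableService", "hasExcludedService")])

    def mk(name, kind, card=1, bound="none", field_hint=None):
        return ConditionDef(
            name=name,
            value_kind=kind,
            max_cardinality=card,
            bound_polarity=bound,
            disjoint_with=frozenset(disjoint.get(name, ())),
            field_hint=field_hint,
        )

    return Ontology(
        [
            mk("hasMaxUnits", "numeric", bound="upper", field_hint="units"),
            mk("hasMinUnits", "numeric", bound="lower", field_hint="units"),
            mk("hasMaxAmount", "numeric", bound="upper", field_hint="billed_amount"),
            mk("hasMinAmount", "numeric", bound="lower", field_hint="billed_amount"),
            mk("hasApplicableService", "code-set", card=math.inf,
               field_hint="procedure_code"),
            mk("hasExcludedService", "code-set", card=math.inf,
               field_hint="procedure_code"),
            mk("hasAmountOfTime", "duration-amount"),
            mk("hasUnitOfTime", "duration-unit"),
            mk("hasSlidingWindowInDays", "numeric", field_hint="service_date"),
            mk("hasMinAge", "numeric", bound="lower", field_hint="birth_date"),
            mk("hasMaxAge", "numeric", bound="upper", field_hint="birth_date"),
            mk("hasBillingCommonality", "categorical", field_hint="provider_id"),
            mk("hasPlaceOfService", "code-set", card=math.inf,
               field_hint="place_of_service"),
        ]
    )


def _parse_json_ontology(text: str, origin: str) -> Ontology:
    try:
        raw = json.loads(text)
    except json.JSONDecodeError as exc:
        raise OntologyFormatError(f"{origin}: line {exc.lineno}: {exc.msg}") from exc
    if not isinstance(raw, dict) or "conditions" not in raw:
        raise OntologyFormatError(f"{origin}: expected an object with a 'conditions' list")
    defs = []
    for entry in raw["conditions"]:
        try:
            card = entry.get("max_cardinality", 1)
            defs.append(
                ConditionDef(
                    name=canonical_name(entry["name"]),
                    value_kind=entry["value_kind"],
                    max_cardinality=math.inf if card in ("unbounded", None) else card,
                    bound_polarity=entry.get("bound_polarity", "none"),
                    disjoint_with=frozenset(
                        canonical_name(n) for n in entry.get("disjoint_with", ())
                    ),
                    field_hint=entry.get("field_hint"),
                )
            )
        except KeyError as exc:
            raise OntologyFormatError(f"{origin}: condition missing key {exc}") from exc
    return Ontology(defs)


def _parse_rdf_ontology(path: Path) -> Ontology:
    graph = rdflib.Graph()
    fmt = "nt" if path.suffix == ".nt" else "turtle"
    try:
        graph.parse(path, format=fmt)
    except Exception as exc:  # rdflib raises assorted parser errors
        raise OntologyFormatError(f"{path}: {exc}") from exc
    defs = []
    for subj in graph.subjects(RDF.type, CR.ConditionProperty):
        name = canonical_name(str(subj).rsplit("#", 1)[-1])
        kind = graph.value(subj, CR.valueKind)
        if kind is None:
            raise OntologyFormatError(f"{path}: {name} lacks a cr:valueKind triple")
        card = graph.value(subj, CR.maxCardinality)
        bound = graph.value(subj, CR.boundPolarity)
        hint = graph.value(subj, CR.fieldHint)
        disjoint = frozenset(
            canonical_name(str(o).rsplit("#", 1)[-1])
            for o in graph.objects(subj, CR.disjointWith)
        )
        defs.append(
            ConditionDef(
                name=name,
                value_kind=str(kind),
                max_cardinality=math.inf if card is None else float(card),
                bound_polarity=str(bound) if bound is not None else "none",
                disjoint_with=disjoint,
                field_hint=str(hint) if hint is not None else None,
            )
        )
    if not defs:
        raise OntologyFormatError(f"{path}: no cr:ConditionProperty declarations found")
    return Ontology(defs)


def load_ontology(path: str | Path) -> Ontology:
    """Load a condition vocabulary.

    ``path`` may be the sentinel ``"builtin"`` (returns the bundled
    vocabulary), a JSON file, or an RDF file (``.ttl`` / ``.nt``).
    """
    if str(path) == "builtin":
        return builtin_ontology()
    p = Path(path)
    if not p.exists():
        raise OntologyFormatError(f"no such ontology file: {p}")
    if p.suffix in {".ttl", ".nt"}:
        return _parse_rdf_ontology(p)
    return _parse_json_ontology(p.read_text(), str(p))
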