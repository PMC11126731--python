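"""Rule knowledge-graph model: conditions, rules, rule sets, validation.

A rule is a conjunction of typed conditions; each condition carries a set
of values interpreted as a disjunction.  Every rule graph is a tree whose
leaves are condition values, which keeps the representation both
machine-executable and renderable for human review.

Constraint violations found by :func:`validate_rule` are returned as data,
not raised: the intended workflow surfaces imperfect rules to an analyst
for curation rather than dropping them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

from .errors import ConsistencyError
from .ontology import Ontology, canonical_name

__all__ = [
    "Scalar",
    "Condition",
    "RuleSource",
    "Rule",
    "RuleSet",
    "Violation",
    "validate_rule",
    "RULE_TYPES",
    "POLARITIES",
]

Scalar = int | float | str

RULE_TYPES = ("service_limitation", "mutual_exclusion", "non_coverage")
POLARITIES = ("compliance", "non_compliance")


@dataclass(frozen=True)
class Condition:
    """One condition of a rule: a property name plus a non-empty ordered
    value set (multiple values are a disjunction).

    ``exclusive`` marks a lower bound that must be strictly exceeded; it is
    only ever set by normalization when inverting a monetary cap.
    """

    def_name: str
    values: tuple[Scalar, ...]
    exclusive: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "def_name", canonical_name(self.def_name))
        if not self.values:
            raise ValueError(f"{self.def_name}: condition values must be non-empty")
        object.__setattr__(self, "values", tuple(self.values))

    @property
    def single_value(self) -> Scalar:
        if len(self.values) != 1:
            raise ValueError(f"{self.def_name}: expected a single value")
        return self.values[0]

    def value_set(self) -> frozenset[str]:
        """Values as strings, for set-overlap comparisons."""
        return frozenset(_value_key(v) for v in self.values)


def _value_key(v: Scalar) -> str:
    # 1 and 1.0 compare equal as set members; strings stay verbatim.
    if isinstance(v, bool):
        return str(v)
    if isinstance(v, (int, float)):
        return repr(float(v))
    return str(v)


@dataclass(frozen=True)
class RuleSource:
    """Provenance of a rule: the policy document and text fragment it encodes."""

    document: str
    fragment: str
    text: str = ""


@dataclass(frozen=True)
class Rule:
    """A policy rule: conjunction of conditions with type, polarity and source."""

    id: str
    rule_type: str
    polarity: str
    conditions: tuple[Condition, ...]
    source: RuleSource | None = None

    def __post_init__(self) -> None:
        if self.rule_type not in RULE_TYPES:
            raise ValueError(f"{self.id}: unknown rule type {self.rule_type!r}")
        if self.polarity not in POLARITIES:
            raise ValueError(f"{self.id}: unknown polarity {self.polarity!r}")
        object.__setattr__(self, "conditions", tuple(self.conditions))

    def condition_names(self) -> frozenset[str]:
        """The set of condition property names (structure of the rule)."""
        return frozenset(c.def_name for c in self.conditions)

    def conditions_named(self, name: str) -> tuple[Condition, ...]:
        name = canonical_name(name)
        return tuple(c for c in self.conditions if c.def_name == name)

    def condition(self, name: str) -> Condition | None:
        """The unique condition with this name, or None (raises if several)."""
        found = self.conditions_named(name)
        if len(found) > 1:
            raise ConsistencyError(f"{self.id}: multiple {name} conditions")
        return found[0] if found else None

    def values_of(self, name: str) -> frozenset[str]:
        """Union of the value sets of all conditions with this name."""
        out: set[str] = set()
        for c in self.conditions_named(name):
            out |= c.value_set()
        return frozenset(out)

    def with_conditions(self, conditions: Sequence[Condition]) -> "Rule":
        return replace(self, conditions=tuple(conditions))

    def tree_counts(self) -> tuple[int, int]:
        """(vertex, edge) counts of the rule tree: root, condition nodes,
        value leaves; edges root->condition and condition->value."""
        n_cond = len(self.conditions)
        n_val = sum(len(c.values) for c in self.conditions)
        return 1 + n_cond + n_val, n_cond + n_val


class RuleSet:
    """Rules keyed by unique id, with an optional role (ground-truth vs
    extracted/authored) and a list of rules rejected at parse time."""

    def __init__(
        self,
        rules: Iterable[Rule] = (),
        role: str = "authored",
        rejected: Sequence[tuple[Rule, list["Violation"]]] = (),
    ):
        self._rules: dict[str, Rule] = {}
        for r in rules:
            if r.id in self._rules:
                raise ConsistencyError(f"duplicate rule id {r.id!r}")
            self._rules[r.id] = r
        self.role = role
        self.rejected = list(rejected)

    def __len__(self) -> int:
        return len(self._rules)

    def __iter__(self) -> Iterator[Rule]:
        return iter(self._rules.values())

    def __contains__(self, rule_id: str) -> bool:
        return rule_id in self._rules

    def __getitem__(self, rule_id: str) -> Rule:
        return self._rules[rule_id]

    @property
    def ids(self) -> list[str]:
        return sorted(self._rules)

    def add(self, rule: Rule) -> None:
        if rule.id in self._rules:
            raise ConsistencyError(f"duplicate rule id {rule.id!r}")
        self._rules[rule.id] = rule

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RuleSet):
            return NotImplemented
        if set(self._rules) != set(other._rules):
            return False
        return all(_rules_equal(self._rules[i], other._rules[i]) for i in self._rules)


def _rules_equal(a: Rule, b: Rule) -> bool:
    """Equality up to condition ordering and value ordering."""
    if (a.id, a.rule_type, a.polarity, a.source) != (b.id, b.rule_type, b.polarity, b.source):
        return False
    ka = sorted((c.def_name, tuple(sorted(c.value_set())), c.exclusive) for c in a.conditions)
    kb = sorted((c.def_name, tuple(sorted(c.value_set())), c.exclusive) for c in b.conditions)
    return ka == kb


@dataclass(frozen=True)
class Violation:
    """One constraint violation found in a rule."""

    kind: str  # "unknown-property" | "cardinality" | "disjointness" | "arity"
    conditions: tuple[str, ...]
    message: str


def validate_rule(rule: Rule, ontology: Ontology) -> list[Violation]:
    """Check a rule against the ontology's constraints.

    Returns a deterministic (sorted by condition name) list of violations;
    empty iff the rule satisfies every constraint.
    """
    violations: list[Violation] = []

    for cond in rule.conditions:
        cdef = ontology.get(cond.def_name)
        if cdef is None:
            violations.append(
                Violation(
                    kind="unknown-property",
                    conditions=(cond.def_name,),
                    message=f"condition property {cond.def_name!r} is not in the ontology",
                )
            )
            continue
        if cdef.is_numeric and len(cond.values) != 1:
            violations.append(
                Violation(
                    kind="arity",
                    conditions=(cond.def_name,),
                    message=f"{cond.def_name} is numeric and must carry exactly one value",
                )
            )

    # Cardinality: number of conditions per property bounded by the def.
    by_name: dict[str, int] = {}
    for cond in rule.conditions:
        by_name[cond.def_name] = by_name.get(cond.def_name, 0) + 1
    for name, count in by_name.items():
        cdef = ontology.get(name)
        if cdef is not None and count > cdef.max_cardinality:
            violations.append(
                Violation(
                    kind="cardinality",
                    conditions=(name,),
                    message=(
                        f"{count} {name} conditions exceed the allowed "
                        f"cardinality of {cdef.max_cardinality:g}"
                    ),
                )
            )

    # Disjointness: value sets of disjoint properties must not overlap.
    names = sorted(by_name)
    for i, a in enumerate(names):
        adef = ontology.get(a)
        if adef is None:
            continue
        for b in names[i + 1:]:
            if b not in adef.disjoint_with:
                continue
            shared = rule.values_of(a) & rule.values_of(b)
            if shared:
                violations.append(
                    Violation(
                        kind="disjointness",
                        conditions=(a, b),
                        message=(
                            f"value(s) {sorted(shared)} appear under both "
                            f"{a} and {b}, which are disjoint"
                        ),
                    )
                )

    violations.sort(key=lambda v: (v.conditions, v.kind))
    return violations
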