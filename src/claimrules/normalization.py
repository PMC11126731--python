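"""Normalization of policy rules into executable non-compliance form.

Three steps, composed by :func:`normalize`:

1. **Polarity inversion** — execution flags violations, so a compliance
   rule ("at most 1 unit is payable") is rewritten as its non-compliance
   complement ("2 or more units are at risk"): ``hasMaxUnits(k)`` becomes
   ``hasMinUnits(k+1)``; a monetary cap ``hasMaxAmount(a)`` becomes an
   exclusive lower bound ``hasMinAmount(a)`` (total strictly above the cap),
   since currency granularity is unknown.
2. **Temporal consolidation** — the (``hasAmountOfTime``,
   ``hasUnitOfTime``) pair becomes a single ``hasSlidingWindowInDays``
   condition; 6 months consolidate to 180 days (month = 30 days,
   week = 7, year = 365; no calendar arithmetic).
3. **Field binding** — each remaining condition is resolved against a
   field map into the claim field and transform the engine reads,
   yielding a :class:`NormalizedRule` ready for pipeline assembly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import yaml

from .errors import (
    BindingError,
    IncompleteRuleError,
    IncompleteTemporalError,
    InvalidBoundError,
    UnknownTimeUnitError,
)
from .model import Condition, Rule

__all__ = [
    "FieldMap",
    "NormalizedRule",
    "Threshold",
    "invert_to_noncompliance",
    "consolidate_temporal",
    "bind_fields",
    "normalize",
    "default_field_map",
    "DAYS_PER_UNIT",
]

DAYS_PER_UNIT: Mapping[str, int] = {"day": 1, "week": 7, "month": 30, "year": 365}

#: Upper-bound condition -> its non-compliance lower-bound counterpart.
_INVERSIONS = {
    "hasMaxUnits": ("hasMinUnits", "count"),
    "hasMaxAmount": ("hasMinAmount", "amount"),
}


@dataclass(frozen=True)
class FieldMap:
    """Mapping from condition property names to (claim field, transform)."""

    entries: Mapping[str, tuple[str, str]]

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def __getitem__(self, name: str) -> tuple[str, str]:
        return self.entries[name]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FieldMap":
        raw = yaml.safe_load(Path(path).read_text())
        entries = {
            name: (spec["field"], spec.get("transform", "identity"))
            for name, spec in raw.items()
        }
        return cls(entries=entries)


def default_field_map() -> FieldMap:
    """The bundled mapping onto the standard claims schema."""
    return FieldMap(
        entries={
            "hasApplicableService": ("procedure_code", "identity"),
            "hasExcludedService": ("procedure_code", "identity"),
            "hasMinUnits": ("units", "sum_units"),
            "hasMaxUnits": ("units", "sum_units"),
            "hasMinAmount": ("billed_amount", "sum_amount"),
            "hasMaxAmount": ("billed_amount", "sum_amount"),
            "hasMinAge": ("birth_date", "age_at_service"),
            "hasMaxAge": ("birth_date", "age_at_service"),
            "hasSlidingWindowInDays": ("service_date", "window_days"),
            "hasBillingCommonality": ("provider_id", "group_key"),
            "hasPlaceOfService": ("place_of_service", "identity"),
        }
    )


@dataclass(frozen=True)
class Threshold:
    """Lower bound the window aggregate must reach (or exceed, if strict)
    for a claim to be flagged."""

    kind: str  # "units" | "amount"
    min_value: float
    strict: bool = False

    def met(self, total: float) -> bool:
        return total > self.min_value if self.strict else total >= self.min_value


@dataclass(frozen=True)
class NormalizedRule:
    """A non-compliance rule with its executable ingredients resolved."""

    base: Rule
    window_days: int | None = None
    group_keys: tuple[str, ...] = ()
    threshold: Threshold | None = None
    service_scope: frozenset[str] = frozenset()
    excluded_scope: frozenset[str] = frozenset()
    age_bounds: tuple[float | None, float | None] = (None, None)

    @property
    def rule_id(self) -> str:
        return self.base.id

    @property
    def rule_type(self) -> str:
        return self.base.rule_type

    @property
    def scope_codes(self) -> frozenset[str]:
        """Codes the rule's filters select (applicable or excluded)."""
        return self.service_scope or self.excluded_scope


def invert_to_noncompliance(rule: Rule) -> Rule:
    """Rewrite a compliance rule as its non-compliance complement.

    ``hasMaxUnits(k)`` -> ``hasMinUnits(k+1)`` (count semantics: the first
    excess unit is the k+1-th); ``hasMaxAmount(a)`` -> exclusive
    ``hasMinAmount(a)``.  Rules already in non-compliance polarity pass
    through unchanged; all other conditions are untouched.
    """
    if rule.polarity == "non_compliance":
        return rule
    out = []
    for cond in rule.conditions:
        inv = _INVERSIONS.get(cond.def_name)
        if inv is None:
            out.append(cond)
            continue
        target, semantics = inv
        k = cond.single_value
        if not isinstance(k, (int, float)) or k <= 0:
            raise InvalidBoundError(
                f"{rule.id}: {cond.def_name} bound must be positive, got {k!r}"
            )
        if semantics == "count":
            out.append(Condition(target, (int(k) + 1,)))
        else:
            out.append(Condition(target, (k,), exclusive=True))
    return replace(rule, polarity="non_compliance", conditions=tuple(out))


def consolidate_temporal(rule: Rule) -> Rule:
    """Replace a (``hasAmountOfTime``, ``hasUnitOfTime``) pair with one
    ``hasSlidingWindowInDays`` condition."""
    amount = rule.condition("hasAmountOfTime")
    unit = rule.condition("hasUnitOfTime")
    if amount is None and unit is None:
        return rule
    if amount is None or unit is None:
        missing = "hasUnitOfTime" if unit is None else "hasAmountOfTime"
        present = "hasAmountOfTime" if unit is None else "hasUnitOfTime"
        raise IncompleteTemporalError(
            f"{rule.id}: {present} without a matching {missing}"
        )
    unit_name = str(unit.single_value).lower().rstrip("s")
    if unit_name not in DAYS_PER_UNIT:
        raise UnknownTimeUnitError(f"{rule.id}: unknown time unit {unit.single_value!r}")
    days = int(round(float(amount.single_value) * DAYS_PER_UNIT[unit_name]))
    kept = [
        c
        for c in rule.conditions
        if c.def_name not in {"hasAmountOfTime", "hasUnitOfTime"}
    ]
    kept.append(Condition("hasSlidingWindowInDays", (days,)))
    return rule.with_conditions(kept)


def bind_fields(rule: Rule, field_map: FieldMap | None = None) -> NormalizedRule:
    """Resolve every condition of a consolidated non-compliance rule
    against the field map, producing a :class:`NormalizedRule`."""
    field_map = field_map or default_field_map()
    if rule.polarity != "non_compliance":
        raise IncompleteRuleError(
            f"{rule.id}: only non-compliance rules can be bound (run inversion first)"
        )
    if rule.condition_names() & {"hasAmountOfTime", "hasUnitOfTime"}:
        raise IncompleteRuleError(
            f"{rule.id}: temporal pair not consolidated (run consolidation first)"
        )

    unmapped = sorted(rule.condition_names() - set(field_map.entries))
    if unmapped:
        raise BindingError(
            f"{rule.id}: no field mapping for condition(s) {', '.join(unmapped)}"
        )

    window = rule.condition("hasSlidingWindowInDays")
    window_days = int(window.single_value) if window else None

    group_keys: list[str] = []
    for cond in rule.conditions_named("hasBillingCommonality"):
        fld, _ = field_map[cond.def_name]
        for v in cond.values:
            if str(v) in {"same_provider", "provider", fld}:
                group_keys.append(fld)
            else:
                raise BindingError(
                    f"{rule.id}: unsupported billing commonality {v!r}"
                )

    threshold = None
    units = rule.condition("hasMinUnits")
    amount = rule.condition("hasMinAmount")
    if units is not None:
        threshold = Threshold("units", float(units.single_value), strict=units.exclusive)
    elif amount is not None:
        threshold = Threshold(
            "amount", float(amount.single_value), strict=amount.exclusive
        )

    if rule.rule_type == "service_limitation" and threshold is None:
        raise IncompleteRuleError(
            f"{rule.id}: service limitation without a unit or amount threshold"
        )

    min_age = rule.condition("hasMinAge")
    max_age = rule.condition("hasMaxAge")

    return NormalizedRule(
        base=rule,
        window_days=window_days,
        group_keys=tuple(dict.fromkeys(group_keys)),
        threshold=threshold,
        service_scope=rule.values_of("hasApplicableService"),
        excluded_scope=rule.values_of("hasExcludedService"),
        age_bounds=(
            float(min_age.single_value) if min_age else None,
            float(max_age.single_value) if max_age else None,
        ),
    )


def normalize(rule: Rule, field_map: FieldMap | None = None) -> NormalizedRule:
    """Full normalization: inversion, temporal consolidation, field binding."""
    return bind_fields(consolidate_temporal(invert_to_noncompliance(rule)), field_map)
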