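"""Execution of normalized rules over per-patient claim histories.

Every rule compiles to an evaluation pipeline of three component kinds:

* **filters** restrict a patient's claim sequence to the claims the rule
  is about (procedure-code scope, age bounds);
* **splitters** partition it — a group-by splitter (e.g. same provider)
  and a sliding-window splitter that yields, for every claim, the
  trailing window of claims within the rule's time span;
* one terminal **evaluator** judges each claim: a cumulative-sum
  evaluator for unit/amount limits, a co-occurrence evaluator for
  mutually exclusive services, and an always-true evaluator for
  non-covered services.

Window semantics: "within W day(s)" means a date difference strictly
below W, so W = 1 selects same-calendar-day claims only (the convention
behind "mutually exclusive within 1 day(s)"); an ``inclusive`` mode
(difference <= W) is available.  The flagged claim is the anchor — the
chronologically last claim of the window in which the threshold is
reached — so the initial, legitimate claims of a history are never
flagged, only the excess ones.  Patients are independent: results never
depend on evaluation order, which is the contract that makes per-patient
parallel execution safe.

:func:`brute_force_flags` is a deliberately naive re-implementation
(subset enumeration and pairwise scans) used as an independent oracle in
tests; it never shares code with the pipeline path.
"""

from __future__ import annotations

import datetime
import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

from .errors import (
    ContextSizeError,
    IncompleteRuleError,
    ParameterError,
    SchemaError,
)
from .normalization import NormalizedRule, Threshold

__all__ = [
    "ClaimRecord",
    "ClaimsDB",
    "EvaluationContext",
    "PipelineComponent",
    "EvaluationPipeline",
    "FlagResult",
    "assemble_pipeline",
    "sliding_windows",
    "run_pipeline",
    "execute_rules",
    "brute_force_flags",
    "age_in_years",
    "CLAIM_FIELDS",
]

CLAIM_FIELDS = (
    "claim_id",
    "patient_id",
    "provider_id",
    "service_date",
    "procedure_code",
    "units",
    "billed_amount",
    "birth_date",
    "place_of_service",
)


def age_in_years(birth_date: datetime.date, on: datetime.date) -> int:
    """Age in completed years on a given date."""
    return on.year - birth_date.year - ((on.month, on.day) < (birth_date.month, birth_date.day))


@dataclass(frozen=True)
class ClaimRecord:
    """One billed service line."""

    claim_id: str
    patient_id: str
    provider_id: str
    service_date: datetime.date
    procedure_code: str
    units: int
    billed_amount: float
    birth_date: datetime.date
    place_of_service: str | None = None

    def __post_init__(self) -> None:
        if self.units < 0:
            raise SchemaError(f"claim {self.claim_id}: negative units")
        if self.billed_amount < 0:
            raise SchemaError(f"claim {self.claim_id}: negative billed amount")
        if self.service_date < self.birth_date:
            raise SchemaError(
                f"claim {self.claim_id}: service date precedes birth date"
            )

    @property
    def sort_key(self) -> tuple[datetime.date, str]:
        return (self.service_date, self.claim_id)

    @property
    def age_at_service(self) -> int:
        return age_in_years(self.birth_date, self.service_date)


def _parse_date(value, claim_id: str, what: str) -> datetime.date:
    if isinstance(value, datetime.date) and not isinstance(value, datetime.datetime):
        return value
    if isinstance(value, (datetime.datetime, pd.Timestamp)):
        return value.date()
    try:
        return datetime.date.fromisoformat(str(value))
    except ValueError as exc:
        raise SchemaError(f"claim {claim_id}: bad {what} {value!r}") from exc


class ClaimsDB:
    """The claims database: one :class:`ClaimRecord` per billed line,
    with per-patient chronological access."""

    def __init__(self, records: Iterable[ClaimRecord]):
        self._records = list(records)
        seen: set[str] = set()
        for r in self._records:
            if r.claim_id in seen:
                raise SchemaError(f"duplicate claim id {r.claim_id!r}")
            seen.add(r.claim_id)
        self._by_id = {r.claim_id: r for r in self._records}

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[ClaimRecord]:
        return iter(self._records)

    def __getitem__(self, claim_id: str) -> ClaimRecord:
        return self._by_id[claim_id]

    def __contains__(self, claim_id: str) -> bool:
        return claim_id in self._by_id

    @property
    def patient_ids(self) -> list[str]:
        return sorted({r.patient_id for r in self._records})

    def context(self, patient_id: str) -> "EvaluationContext":
        claims = sorted(
            (r for r in self._records if r.patient_id == patient_id),
            key=lambda r: r.sort_key,
        )
        return EvaluationContext(patient_id=patient_id, claims=tuple(claims))

    def contexts(self) -> Iterator["EvaluationContext"]:
        by_patient: dict[str, list[ClaimRecord]] = {}
        for r in self._records:
            by_patient.setdefault(r.patient_id, []).append(r)
        for pid in sorted(by_patient):
            claims = sorted(by_patient[pid], key=lambda r: r.sort_key)
            yield EvaluationContext(patient_id=pid, claims=tuple(claims))

    # ------------------------------------------------------------- I/O

    @classmethod
    def from_records(cls, rows: Iterable[dict]) -> "ClaimsDB":
        records = []
        for row in rows:
            cid = str(row.get("claim_id", "<missing>"))
            try:
                pos = row.get("place_of_service")
                if pos is None or (isinstance(pos, float) and pd.isna(pos)) or pos == "":
                    pos = None
                else:
                    pos = str(pos)
                records.append(
                    ClaimRecord(
                        claim_id=cid,
                        patient_id=str(row["patient_id"]),
                        provider_id=str(row["provider_id"]),
                        service_date=_parse_date(row["service_date"], cid, "service date"),
                        procedure_code=str(row["procedure_code"]),
                        units=int(row["units"]),
                        billed_amount=float(row["billed_amount"]),
                        birth_date=_parse_date(row["birth_date"], cid, "birth date"),
                        place_of_service=pos,
                    )
                )
            except KeyError as exc:
                raise SchemaError(f"claim {cid}: missing field {exc}") from exc
            except (TypeError, ValueError) as exc:
                raise SchemaError(f"claim {cid}: {exc}") from exc
        return cls(records)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ClaimsDB":
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
        missing = set(CLAIM_FIELDS[:-1]) - set(frame.columns)
        if missing:
            raise SchemaError(f"{path}: missing column(s) {sorted(missing)}")
        return cls.from_records(frame.to_dict("records"))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "claim_id": r.claim_id,
                "patient_id": r.patient_id,
                "provider_id": r.provider_id,
                "service_date": r.service_date.isoformat(),
                "procedure_code": r.procedure_code,
                "units": r.units,
                "billed_amount": r.billed_amount,
                "birth_date": r.birth_date.isoformat(),
                "place_of_service": r.place_of_service or "",
            }
            for r in sorted(self._records, key=lambda r: (r.patient_id, r.sort_key))
        ]
        return pd.DataFrame(rows, columns=list(CLAIM_FIELDS))

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class EvaluationContext:
    """The chronological claim sequence of one patient (ties broken by
    claim id, so evaluation is deterministic)."""

    patient_id: str
    claims: tuple[ClaimRecord, ...]

    def __post_init__(self) -> None:
        ordered = tuple(sorted(self.claims, key=lambda r: r.sort_key))
        object.__setattr__(self, "claims", ordered)
        for c in ordered:
            if c.patient_id != self.patient_id:
                raise SchemaError(
                    f"claim {c.claim_id} belongs to {c.patient_id}, "
                    f"not {self.patient_id}"
                )

    def __len__(self) -> int:
        return len(self.claims)


# ----------------------------------------------------------- pipeline


@dataclass(frozen=True)
class PipelineComponent:
    """Declarative pipeline component: a filter, splitter, or evaluator."""

    kind: str  # "filter" | "splitter" | "evaluator"
    op: str
    params: tuple = ()


@dataclass(frozen=True)
class EvaluationPipeline:
    """Ordered components for one rule: filters, then splitters, then
    exactly one terminal evaluator."""

    rule_id: str
    components: tuple[PipelineComponent, ...]
    rule: NormalizedRule

    def __post_init__(self) -> None:
        kinds = [c.kind for c in self.components]
        if kinds.count("evaluator") != 1 or kinds[-1] != "evaluator":
            raise IncompleteRuleError(
                f"{self.rule_id}: pipeline must end in exactly one evaluator"
            )
        order = {"filter": 0, "splitter": 1, "evaluator": 2}
        ranks = [order[k] for k in kinds]
        if ranks != sorted(ranks):
            raise IncompleteRuleError(
                f"{self.rule_id}: filters must precede splitters must precede "
                "the evaluator"
            )

    @property
    def filters(self) -> tuple[PipelineComponent, ...]:
        return tuple(c for c in self.components if c.kind == "filter")

    @property
    def evaluator(self) -> PipelineComponent:
        return self.components[-1]


def assemble_pipeline(nrule: NormalizedRule) -> EvaluationPipeline:
    """Compile a normalized rule into its evaluation pipeline."""
    comps: list[PipelineComponent] = []

    if nrule.service_scope:
        comps.append(
            PipelineComponent("filter", "code_in", (frozenset(nrule.service_scope),))
        )
    if nrule.excluded_scope:
        comps.append(
            PipelineComponent("filter", "code_in", (frozenset(nrule.excluded_scope),))
        )
    min_age, max_age = nrule.age_bounds
    if min_age is not None:
        comps.append(PipelineComponent("filter", "age_ge", (min_age,)))
    if max_age is not None:
        comps.append(PipelineComponent("filter", "age_le", (max_age,)))

    if nrule.group_keys:
        comps.append(PipelineComponent("splitter", "group_by", (nrule.group_keys,)))
    if nrule.window_days is not None:
        if nrule.window_days <= 0:
            raise ParameterError(f"{nrule.rule_id}: window must be positive")
        comps.append(
            PipelineComponent("splitter", "sliding_window", (nrule.window_days,))
        )

    if nrule.rule_type == "mutual_exclusion":
        comps.append(
            PipelineComponent("evaluator", "co_occurrence", (frozenset(nrule.scope_codes),))
        )
    elif nrule.rule_type == "non_coverage":
        comps.append(PipelineComponent("evaluator", "always_true"))
    else:
        if nrule.threshold is None:
            raise IncompleteRuleError(
                f"{nrule.rule_id}: no evaluator derivable (missing threshold)"
            )
        comps.append(
            PipelineComponent("evaluator", "cumulative_sum", (nrule.threshold,))
        )

    return EvaluationPipeline(
        rule_id=nrule.rule_id, components=tuple(comps), rule=nrule
    )


@dataclass(frozen=True)
class FlagResult:
    """A claim flagged as at-risk, with its triggering evidence."""

    claim_id: str
    rule_id: str
    patient_id: str
    flagged: bool
    triggering_claim_ids: tuple[str, ...] = ()
    triggering_dates: tuple[str, ...] = ()
    evidence: dict = field(default_factory=dict)


def _apply_filter(comp: PipelineComponent, claim: ClaimRecord) -> bool:
    if comp.op == "code_in":
        return claim.procedure_code in comp.params[0]
    if comp.op == "age_ge":
        return claim.age_at_service >= comp.params[0]
    if comp.op == "age_le":
        return claim.age_at_service <= comp.params[0]
    raise ParameterError(f"unknown filter op {comp.op!r}")


def _window_limit(window_days: int | None, mode: str) -> int | None:
    if window_days is None:
        return None
    if window_days <= 0:
        raise ParameterError("window_days must be positive")
    if mode == "inclusive":
        return window_days + 1
    if mode != "strict":
        raise ParameterError(f"unknown window mode {mode!r}")
    return window_days


def sliding_windows(
    ctx: EvaluationContext, window_days: int, window_mode: str = "strict"
) -> Iterator[EvaluationContext]:
    """One trailing window per anchor claim: all claims dated within
    ``window_days`` before (or on the same day as) the anchor."""
    limit = _window_limit(window_days, window_mode)
    for anchor in ctx.claims:
        members = tuple(
            c
            for c in ctx.claims
            if 0 <= (anchor.service_date - c.service_date).days < limit
        )
        yield EvaluationContext(patient_id=ctx.patient_id, claims=members)


def _group_claims(
    claims: Sequence[ClaimRecord], group_keys: Sequence[str]
) -> list[tuple[ClaimRecord, ...]]:
    if not group_keys:
        return [tuple(claims)]
    groups: dict[tuple, list[ClaimRecord]] = {}
    for c in claims:
        key = tuple(getattr(c, k) for k in group_keys)
        groups.setdefault(key, []).append(c)
    return [tuple(groups[k]) for k in sorted(groups)]


def run_pipeline(
    pipeline: EvaluationPipeline,
    ctx: EvaluationContext,
    window_mode: str = "strict",
) -> list[FlagResult]:
    """Execute one rule pipeline over one patient context.

    Returns one :class:`FlagResult` per flagged claim (each claim anchors
    exactly one window, so flags are unique per claim).
    """
    nrule = pipeline.rule
    survivors = [
        c for c in ctx.claims if all(_apply_filter(f, c) for f in pipeline.filters)
    ]
    limit = _window_limit(nrule.window_days, window_mode)
    results: list[FlagResult] = []

    for group in _group_claims(survivors, nrule.group_keys):
        ordered = sorted(group, key=lambda c: c.sort_key)
        for i, anchor in enumerate(ordered):
            in_window = [
                c
                for c in ordered
                if limit is None
                or 0 <= (anchor.service_date - c.service_date).days < limit
            ]
            flag = _evaluate(pipeline.evaluator, nrule, anchor, in_window)
            if flag is None:
                continue
            evidence, trigger = flag
            results.append(
                FlagResult(
                    claim_id=anchor.claim_id,
                    rule_id=nrule.rule_id,
                    patient_id=ctx.patient_id,
                    flagged=True,
                    triggering_claim_ids=tuple(c.claim_id for c in trigger),
                    triggering_dates=tuple(
                        c.service_date.isoformat() for c in trigger
                    ),
                    evidence=evidence,
                )
            )
    results.sort(key=lambda f: f.claim_id)
    return results


def _evaluate(
    evaluator: PipelineComponent,
    nrule: NormalizedRule,
    anchor: ClaimRecord,
    in_window: list[ClaimRecord],
) -> tuple[dict, list[ClaimRecord]] | None:
    """Judge one anchor claim inside its window; None when compliant."""
    if evaluator.op == "cumulative_sum":
        threshold: Threshold = evaluator.params[0]
        # Running total in chronological order, anchor last: same-day
        # claims sorted after the anchor do not count toward its total.
        prefix = [c for c in in_window if c.sort_key <= anchor.sort_key]
        total = sum(
            (c.units if threshold.kind == "units" else c.billed_amount)
            for c in prefix
        )
        if threshold.met(total):
            return (
                {
                    "aggregate": total,
                    "threshold": threshold.min_value,
                    "strict": threshold.strict,
                    "kind": threshold.kind,
                },
                prefix,
            )
        return None
    if evaluator.op == "co_occurrence":
        others = [
            c
            for c in in_window
            if c.claim_id != anchor.claim_id
            and c.procedure_code != anchor.procedure_code
        ]
        if others:
            return (
                {
                    "codes": tuple(
                        sorted({anchor.procedure_code}
                               | {c.procedure_code for c in others})
                    )
                },
                [anchor] + others,
            )
        return None
    if evaluator.op == "always_true":
        return {"code": anchor.procedure_code}, [anchor]
    raise ParameterError(f"unknown evaluator op {evaluator.op!r}")


def execute_rules(
    rules: Sequence[NormalizedRule],
    claims: ClaimsDB,
    window_mode: str = "strict",
) -> list[FlagResult]:
    """Run every rule over every patient context.

    Patients are evaluated independently, so the result is identical to
    any parallel execution order; output is sorted by (rule id, patient
    id, claim id).
    """
    results: list[FlagResult] = []
    pipelines = [assemble_pipeline(r) for r in rules]
    contexts = list(claims.contexts())
    for pipeline in pipelines:
        for ctx in contexts:
            results.extend(run_pipeline(pipeline, ctx, window_mode))
    results.sort(key=lambda f: (f.rule_id, f.patient_id, f.claim_id))
    return results


# ------------------------------------------------------------- oracle


def brute_force_flags(
    nrule: NormalizedRule,
    ctx: EvaluationContext,
    window_mode: str = "strict",
    max_claims: int = 20,
) -> set[str]:
    """Independent oracle: apply the rule predicate by direct enumeration.

    Service limitations enumerate *every* subset of the filtered claims
    whose date span fits the window and flag the subset's last claim when
    the subset total meets the threshold; mutual exclusions scan all
    ordered claim pairs; non-coverage applies the filters directly.
    Exponential in context size, hence the guard.
    """
    if len(ctx) > max_claims:
        raise ContextSizeError(
            f"brute force limited to {max_claims} claims, got {len(ctx)}"
        )
    limit = _window_limit(nrule.window_days, window_mode)

    def keep(c: ClaimRecord) -> bool:
        if nrule.service_scope and c.procedure_code not in nrule.service_scope:
            return False
        if nrule.excluded_scope and c.procedure_code not in nrule.excluded_scope:
            return False
        lo, hi = nrule.age_bounds
        if lo is not None and c.age_at_service < lo:
            return False
        if hi is not None and c.age_at_service > hi:
            return False
        return True

    eligible = [c for c in ctx.claims if keep(c)]
    flagged: set[str] = set()

    groups: dict[tuple, list[ClaimRecord]] = {}
    for c in eligible:
        key = tuple(getattr(c, k) for k in nrule.group_keys)
        groups.setdefault(key, []).append(c)

    for group in groups.values():
        if nrule.rule_type == "non_coverage":
            flagged.update(c.claim_id for c in group)
            continue
        if nrule.rule_type == "mutual_exclusion":
            # windowed: a is flagged when some differing-code claim falls in
            # its trailing window; without a window, any differing pair
            # flags both claims.
            for a, b in itertools.permutations(group, 2):
                if a.procedure_code == b.procedure_code:
                    continue
                gap = (a.service_date - b.service_date).days
                if limit is None or 0 <= gap < limit:
                    flagged.add(a.claim_id)
            continue
        # service limitation: subset enumeration
        threshold = nrule.threshold
        for r in range(1, len(group) + 1):
            for subset in itertools.combinations(group, r):
                dates = [c.service_date for c in subset]
                span = (max(dates) - min(dates)).days
                if limit is not None and span >= limit:
                    continue
                last = max(subset, key=lambda c: c.sort_key)
                if limit is not None:
                    # subset must sit inside the last claim's trailing window
                    if any(
                        (last.service_date - c.service_date).days >= limit
                        for c in subset
                    ):
                        continue
                total = sum(
                    c.units if threshold.kind == "units" else c.billed_amount
                    for c in subset
                )
                if threshold.met(total):
                    flagged.add(last.claim_id)
    return flagged
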