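"""Human-readable explanations and aggregate statistics for flagged claims.

Each flag renders to a one-sentence explanation naming the concrete codes
and values that triggered it, e.g. for a mutual exclusion:
``"D4355 and D1110 are mutually exclusive within 1 day(s)"``.  Aggregate
reports summarize an execution run: total distinct claims at risk, their
estimated value (sum of billed amounts, de-duplicated by claim), and
per-patient / per-rule / per-age distributions.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .engine import ClaimsDB, FlagResult, age_in_years
from .errors import ConsistencyError
from .model import Rule

__all__ = [
    "Explanation",
    "AggregateReport",
    "explain_flag",
    "aggregate_report",
    "write_report",
    "report_from_json",
    "percentage",
]


def percentage(part: float, whole: float, digits: int = 2) -> float:
    """Share of ``part`` in ``whole`` as a percentage, rounded for display."""
    if whole == 0:
        return 0.0
    return round(100.0 * part / whole, digits)


@dataclass(frozen=True)
class Explanation:
    """One flag with its rendered sentence and rule context."""

    claim_id: str
    rule_id: str
    text: str
    rule_summary: str
    source_fragment: str = ""


def _number(x: float) -> str:
    return f"{int(x)}" if float(x) == int(x) else f"{x:g}"


def _rule_summary(rule: Rule) -> str:
    parts = [
        f"{c.def_name}({', '.join(str(v) for v in c.values)})"
        for c in rule.conditions
    ]
    return f"{rule.rule_type.replace('_', ' ')}: " + " AND ".join(parts)


def explain_flag(flag: FlagResult, rule: Rule) -> Explanation:
    """Render a one-sentence explanation for one flagged claim.

    Output is byte-stable for fixed inputs; the mutual-exclusion sentence
    lists the service pair in the order the rule declares it.
    """
    if flag.rule_id != rule.id:
        raise ConsistencyError(
            f"flag on rule {flag.rule_id!r} cannot be explained by rule {rule.id!r}"
        )
    window = None
    wcond = rule.condition("hasSlidingWindowInDays")
    if wcond is None and rule.condition("hasAmountOfTime") is not None:
        # curated rules may still carry the raw (amount, unit) pair
        from .normalization import consolidate_temporal

        wcond = consolidate_temporal(rule).condition("hasSlidingWindowInDays")
    if wcond is not None:
        window = int(wcond.single_value)

    if rule.rule_type == "mutual_exclusion":
        codes = []
        for cond in rule.conditions:
            if cond.def_name in {"hasApplicableService", "hasExcludedService"}:
                codes.extend(str(v) for v in cond.values)
        if len(codes) < 2:
            codes = list(flag.evidence.get("codes", ()))
        pair = " and ".join(codes[:2]) if len(codes) >= 2 else codes[0]
        suffix = f" within {window} day(s)" if window is not None else ""
        text = f"{pair} are mutually exclusive{suffix}"
    elif rule.rule_type == "non_coverage":
        code = flag.evidence.get("code", "service")
        quals = []
        min_age = rule.condition("hasMinAge")
        max_age = rule.condition("hasMaxAge")
        if max_age is not None:
            quals.append(f"for patients up to {_number(max_age.single_value)} year(s) of age")
        if min_age is not None:
            quals.append(f"for patients from {_number(min_age.single_value)} year(s) of age")
        qualifier = " " + " and ".join(quals) if quals else ""
        text = f"{code} is not covered{qualifier}"
    else:  # service limitation
        code = None
        scope = sorted(rule.values_of("hasApplicableService"))
        if len(scope) == 1:
            code = scope[0]
        elif flag.evidence.get("codes"):
            code = flag.evidence["codes"][0]
        subject = code if code is not None else "service"
        aggregate = flag.evidence.get("aggregate", 0)
        threshold = flag.evidence.get("threshold", 0)
        kind = flag.evidence.get("kind", "units")
        span = f" within {window} day(s)" if window is not None else ""
        if kind == "amount":
            # the monetary cap is the bound itself (exclusive lower bound)
            text = (
                f"{subject}: {_number(aggregate)} billed{span} "
                f"exceeds the allowed {_number(threshold)}"
            )
        else:
            allowed = threshold - 1  # min non-compliant count k+1 -> allowed k
            text = (
                f"{subject}: {_number(aggregate)} unit(s) billed{span} "
                f"exceeds the allowed {_number(allowed)}"
            )

    return Explanation(
        claim_id=flag.claim_id,
        rule_id=rule.id,
        text=text,
        rule_summary=_rule_summary(rule),
        source_fragment=rule.source.text if rule.source else "",
    )


@dataclass(frozen=True)
class AggregateReport:
    """Aggregated statistics over an execution run."""

    total_flagged: int
    estimated_value: float
    per_patient_counts: dict[str, int] = field(default_factory=dict)
    per_rule_counts: dict[str, int] = field(default_factory=dict)
    age_by_flags: tuple[tuple[int, int], ...] = ()

    def to_dict(self) -> dict:
        return {
            "total_flagged": self.total_flagged,
            "estimated_value": self.estimated_value,
            "per_patient_counts": dict(sorted(self.per_patient_counts.items())),
            "per_rule_counts": dict(sorted(self.per_rule_counts.items())),
            "age_by_flags": [list(t) for t in self.age_by_flags],
        }


def aggregate_report(flags: Sequence[FlagResult], claims: ClaimsDB) -> AggregateReport:
    """Summarize flags: distinct claims at risk, estimated value, and
    distributions per patient, per rule, and by patient age at service."""
    for f in flags:
        if f.claim_id not in claims:
            raise ConsistencyError(f"flag references unknown claim {f.claim_id!r}")

    distinct = sorted({f.claim_id for f in flags if f.flagged})
    value = sum(claims[cid].billed_amount for cid in distinct)

    per_patient = Counter(claims[cid].patient_id for cid in distinct)
    per_rule = Counter(f.rule_id for f in flags if f.flagged)

    age_counter: Counter[int] = Counter()
    for cid in distinct:
        rec = claims[cid]
        age_counter[age_in_years(rec.birth_date, rec.service_date)] += 1

    return AggregateReport(
        total_flagged=len(distinct),
        estimated_value=round(value, 2),
        per_patient_counts=dict(sorted(per_patient.items())),
        per_rule_counts=dict(sorted(per_rule.items())),
        age_by_flags=tuple(sorted(age_counter.items())),
    )


def write_report(
    report: AggregateReport,
    explanations: Sequence[Explanation],
    path: str | Path,
    format: str = "json",
) -> None:
    """Write a report (with its explanations) as JSON, TSV, or plain text."""
    p = Path(path)
    if format == "json":
        doc = {
            "report": report.to_dict(),
            "explanations": [
                {
                    "claim_id": e.claim_id,
                    "rule_id": e.rule_id,
                    "text": e.text,
                    "rule_summary": e.rule_summary,
                    "source_fragment": e.source_fragment,
                }
                for e in explanations
            ],
        }
        p.write_text(json.dumps(doc, indent=2) + "\n")
    elif format == "tsv":
        lines = ["claim_id\trule_id\texplanation"]
        lines += [f"{e.claim_id}\t{e.rule_id}\t{e.text}" for e in explanations]
        p.write_text("\n".join(lines) + "\n")
    elif format == "text":
        lines = [
            f"Claims at risk: {report.total_flagged}",
            f"Estimated value: {report.estimated_value:.2f}",
            "",
        ]
        lines += [f"  [{e.rule_id}] {e.claim_id}: {e.text}" for e in explanations]
        p.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown report format {format!r}")


def report_from_json(path: str | Path) -> tuple[AggregateReport, list[Explanation]]:
    """Read back a JSON report written by :func:`write_report`."""
    doc = json.loads(Path(path).read_text())
    rep = doc["report"]
    report = AggregateReport(
        total_flagged=rep["total_flagged"],
        estimated_value=rep["estimated_value"],
        per_patient_counts=rep["per_patient_counts"],
        per_rule_counts=rep["per_rule_counts"],
        age_by_flags=tuple((a, n) for a, n in rep["age_by_flags"]),
    )
    explanations = [Explanation(**e) for e in doc["explanations"]]
    return report, explanations
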