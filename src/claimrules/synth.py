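"""Seeded synthetic claims with planted rule violations.

The generator builds a schema-valid claims database in two stages:

1. :func:`generate_background` constructs per-patient claim histories
   that are *clean by construction*: every candidate claim is checked
   against every rule before placement (falling back to codes outside
   all rule scopes when a placement would violate), and the finished
   database is verified with the execution engine.  Cleanliness is
   therefore provable, not probabilistic.
2. :func:`plant_violations` inserts minimal violating claim patterns —
   an excess claim inside a service-limitation window, a same-day
   mutually-exclusive pair, a non-covered service for an eligible
   patient — and records exactly the claim ids the engine's anchor
   convention flags.

The result is a :class:`LabelledClaimsDB` whose planted labels are, by
construction, precisely the engine's flag set, which makes it the
package's ground truth for end-to-end precision/recall checks.

The default rule set (:func:`example_rules`) covers all three rule
types with standard CDT-style dental codes: a once-per-180-days
limitation on D0145, the D4355/D1110 same-day mutual exclusion, and an
age-bounded non-covered service.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field, replace

import numpy as np

from .engine import ClaimRecord, ClaimsDB, execute_rules
from .errors import GenerationError, PlantingError
from .model import Condition, Rule, RuleSet, RuleSource
from .normalization import NormalizedRule, normalize

__all__ = [
    "SyntheticConfig",
    "LabelledClaimsDB",
    "example_rules",
    "generate_background",
    "plant_violations",
    "generate_dataset",
]

_DEFAULT_VOCAB = (
    # codes referenced by the example rules
    "D0145", "D1110", "D4355", "D9999",
    # filler codes outside every example-rule scope
    "D0120", "D0274", "D1206", "D2140", "D2150", "D7140",
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic database."""

    n_patients: int = 1000
    date_range: tuple[datetime.date, datetime.date] = (
        datetime.date(2019, 1, 1),
        datetime.date(2020, 12, 31),
    )
    code_vocabulary: tuple[str, ...] = _DEFAULT_VOCAB
    claims_per_patient: tuple[int, int] = (2, 8)
    violations_to_plant: tuple[tuple[str, int], ...] = (
        ("SL-D0145-180d", 30),
        ("ME-D4355-D1110", 20),
        ("NC-D9999-age", 16),
    )
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be non-negative")
        if self.date_range[0] > self.date_range[1]:
            raise ValueError("empty date range")
        lo, hi = self.claims_per_patient
        if lo < 0 or hi < lo:
            raise ValueError("bad claims_per_patient bounds")


@dataclass(frozen=True)
class LabelledClaimsDB:
    """A claims database together with its planted ground-truth labels."""

    claims: ClaimsDB
    planted: frozenset[tuple[str, str]] = frozenset()  # (claim_id, rule_id)

    def labels_for(self, rule_id: str) -> frozenset[str]:
        return frozenset(c for c, r in self.planted if r == rule_id)


def example_rules() -> RuleSet:
    """Three policy rules covering all rule types, with source provenance."""
    limitation = Rule(
        id="SL-D0145-180d",
        rule_type="service_limitation",
        polarity="compliance",
        conditions=(
            Condition("hasApplicableService", ("D0145",)),
            Condition("hasMaxUnits", (1,)),
            Condition("hasAmountOfTime", (6,)),
            Condition("hasUnitOfTime", ("month",)),
        ),
        source=RuleSource(
            document="synthetic-dental-policy",
            fragment="frag-limitation",
            text=(
                "An oral evaluation for children and counseling with the "
                "primary caregiver (D0145) is payable once in a six-month period."
            ),
        ),
    )
    exclusion = Rule(
        id="ME-D4355-D1110",
        rule_type="mutual_exclusion",
        polarity="non_compliance",
        conditions=(
            Condition("hasApplicableService", ("D4355", "D1110")),
            Condition("hasSlidingWindowInDays", (1,)),
        ),
        source=RuleSource(
            document="synthetic-dental-policy",
            fragment="frag-exclusion",
            text=(
                "Full mouth debridement (D4355) and prophylaxis (D1110) are "
                "not reimbursable together on the same date of service."
            ),
        ),
    )
    non_coverage = Rule(
        id="NC-D9999-age",
        rule_type="non_coverage",
        polarity="non_compliance",
        conditions=(
            Condition("hasExcludedService", ("D9999",)),
            Condition("hasMaxAge", (20,)),
        ),
        source=RuleSource(
            document="synthetic-dental-policy",
            fragment="frag-noncoverage",
            text=(
                "Unspecified adjunctive procedures (D9999) are not a covered "
                "benefit for members twenty years of age or younger."
            ),
        ),
    )
    return RuleSet([limitation, exclusion, non_coverage], role="ground-truth")


# ------------------------------------------------------- safety check


def _group_match(nrule: NormalizedRule, a: ClaimRecord, b: ClaimRecord) -> bool:
    return all(getattr(a, k) == getattr(b, k) for k in nrule.group_keys)


def _in_scope(nrule: NormalizedRule, claim: ClaimRecord) -> bool:
    scope = nrule.scope_codes
    if scope and claim.procedure_code not in scope:
        return False
    lo, hi = nrule.age_bounds
    if lo is not None and claim.age_at_service < lo:
        return False
    if hi is not None and claim.age_at_service > hi:
        return False
    return True


def _conflicts(
    nrule: NormalizedRule,
    existing: list[ClaimRecord],
    candidate: ClaimRecord,
) -> bool:
    """Would adding ``candidate`` let ``nrule`` flag any claim?

    Conservative: may reject a safe placement, never accepts an unsafe
    one.  Any evaluation window that contains the candidate lies entirely
    within ``window_days`` of it, so scanning that neighbourhood bounds
    every affected window total.
    """
    if not _in_scope(nrule, candidate):
        return False
    if nrule.rule_type == "non_coverage":
        return True
    near = [
        c
        for c in existing
        if _in_scope(nrule, c)
        and _group_match(nrule, c, candidate)
        and (
            nrule.window_days is None
            or abs((c.service_date - candidate.service_date).days) < nrule.window_days
        )
    ]
    if nrule.rule_type == "mutual_exclusion":
        return any(c.procedure_code != candidate.procedure_code for c in near)
    threshold = nrule.threshold
    if threshold.kind == "units":
        total = candidate.units + sum(c.units for c in near)
    else:
        total = candidate.billed_amount + sum(c.billed_amount for c in near)
    return threshold.met(total)


def _safe_codes(config: SyntheticConfig, rules: list[NormalizedRule]) -> list[str]:
    constrained: set[str] = set()
    for r in rules:
        constrained |= set(r.service_scope) | set(r.excluded_scope)
    return [c for c in config.code_vocabulary if c not in constrained]


# --------------------------------------------------------- generation


def _random_date(rng, start: datetime.date, end: datetime.date) -> datetime.date:
    span = (end - start).days
    return start + datetime.timedelta(days=int(rng.integers(0, span + 1)))


def generate_background(
    config: SyntheticConfig, rules: list[NormalizedRule]
) -> ClaimsDB:
    """A clean background database: no rule in ``rules`` flags any claim."""
    rng = np.random.default_rng(config.seed)
    safe_codes = _safe_codes(config, rules)
    if not safe_codes:
        raise GenerationError(
            "no procedure code in the vocabulary is free of rule constraints"
        )
    start, end = config.date_range
    records: list[ClaimRecord] = []
    seq = 0
    for p in range(config.n_patients):
        pid = f"P{p:05d}"
        age = int(rng.integers(1, 81))
        birth = datetime.date(start.year - age, int(rng.integers(1, 13)), int(rng.integers(1, 29)))
        providers = [f"PR{int(i):03d}" for i in rng.integers(0, 20, size=2)]
        n_claims = int(rng.integers(config.claims_per_patient[0], config.claims_per_patient[1] + 1))
        mine: list[ClaimRecord] = []
        for _ in range(n_claims):
            code = str(rng.choice(config.code_vocabulary))
            candidate = ClaimRecord(
                claim_id=f"C{seq:07d}",
                patient_id=pid,
                provider_id=str(rng.choice(providers)),
                service_date=_random_date(rng, start, end),
                procedure_code=code,
                units=1,
                billed_amount=float(rng.integers(40, 260)),
                birth_date=birth,
                place_of_service="11",
            )
            if any(_conflicts(r, mine, candidate) for r in rules):
                candidate = replace(candidate, procedure_code=str(rng.choice(safe_codes)))
            mine.append(candidate)
            seq += 1
        records.extend(mine)

    db = ClaimsDB(records)
    stray = execute_rules(rules, db)
    if stray:
        raise GenerationError(
            f"background construction left {len(stray)} flagged claim(s); "
            "config is too tight"
        )
    return db


# ----------------------------------------------------------- planting


class _Planter:
    def __init__(self, db: ClaimsDB, rules: list[NormalizedRule], rng):
        self.rules = rules
        self.rng = rng
        self.records = list(db)
        self.by_patient: dict[str, list[ClaimRecord]] = {}
        for r in self.records:
            self.by_patient.setdefault(r.patient_id, []).append(r)
        self.used_patients: set[str] = set()
        self.seq = 0
        self.planted: set[tuple[str, str]] = set()

    def next_id(self) -> str:
        self.seq += 1
        return f"V{self.seq:05d}"

    def eligible_patients(self, nrule: NormalizedRule) -> list[str]:
        """Patients with no claims touching the rule's scope, so the plant
        interacts with nothing."""
        scope = nrule.scope_codes
        out = []
        for pid, claims in self.by_patient.items():
            if pid in self.used_patients:
                continue
            if any(c.procedure_code in scope for c in claims):
                continue
            out.append(pid)
        return sorted(out)

    def insert(self, nrule: NormalizedRule, claims: list[ClaimRecord], flagged: list[str]) -> None:
        # a plant must not trip any *other* rule
        for other in self.rules:
            if other.rule_id == nrule.rule_id:
                continue
            placed: list[ClaimRecord] = list(self.by_patient[claims[0].patient_id])
            for c in claims:
                if _conflicts(other, placed, c):
                    raise PlantingError(
                        f"plant for {nrule.rule_id} would also violate {other.rule_id}"
                    )
                placed.append(c)
        self.records.extend(claims)
        self.by_patient[claims[0].patient_id].extend(claims)
        self.used_patients.add(claims[0].patient_id)
        self.planted.update((cid, nrule.rule_id) for cid in flagged)


def _plant_limitation(
    planter: _Planter,
    nrule: NormalizedRule,
    count: int,
    date_range: tuple[datetime.date, datetime.date],
) -> None:
    if not nrule.service_scope:
        raise PlantingError(f"{nrule.rule_id}: no applicable service to plant")
    code = sorted(nrule.service_scope)[0]
    threshold = nrule.threshold
    window = nrule.window_days
    # excess claim lands inside the window (same day when the window is 1 day)
    gap = 1 if window is None else max(0, min(30, window - 1))
    patients = planter.eligible_patients(nrule)
    if len(patients) < count:
        raise PlantingError(
            f"{nrule.rule_id}: only {len(patients)} eligible patients for {count} plants"
        )
    start, end = date_range
    for pid in patients[:count]:
        base = planter.by_patient[pid][0]
        d0 = min(start + datetime.timedelta(days=int(planter.rng.integers(0, 120))), end)
        d1 = min(d0 + datetime.timedelta(days=gap), end)
        if threshold.kind == "units":
            first_units, first_amount = max(1, int(threshold.min_value) - 1), 75.0
            second_units, second_amount = 1, 75.0
        else:
            first_units, first_amount = 1, float(threshold.min_value)
            second_units, second_amount = 1, 1.0
        first = ClaimRecord(
            claim_id=planter.next_id(), patient_id=pid, provider_id=base.provider_id,
            service_date=d0, procedure_code=code, units=first_units,
            billed_amount=first_amount, birth_date=base.birth_date,
            place_of_service=base.place_of_service,
        )
        second = ClaimRecord(
            claim_id=planter.next_id(), patient_id=pid, provider_id=base.provider_id,
            service_date=d1, procedure_code=code, units=second_units,
            billed_amount=second_amount, birth_date=base.birth_date,
            place_of_service=base.place_of_service,
        )
        # anchor convention: only the excess (second) claim is flagged
        planter.insert(nrule, [first, second], [second.claim_id])


def _plant_exclusion(
    planter: _Planter,
    nrule: NormalizedRule,
    count: int,
    date_range: tuple[datetime.date, datetime.date],
) -> None:
    codes = sorted(nrule.scope_codes)
    if len(codes) < 2:
        raise PlantingError(f"{nrule.rule_id}: needs a pair of exclusive codes")
    c1, c2 = codes[0], codes[1]
    window = nrule.window_days
    same_day_only = window == 1
    start, end = date_range

    # same-day pairs flag both anchors (2 per plant); a cross-day pair
    # flags only the later claim (1 per plant) when the window allows it
    plants: list[tuple[int, int]] = []  # (n_claims spec marker, flags)
    remaining = count
    if same_day_only:
        if count == 1:
            raise PlantingError(
                f"{nrule.rule_id}: a same-day exclusive pair always flags both "
                "claims; cannot plant exactly 1"
            )
        while remaining >= 2:
            if remaining == 3:
                plants.append((3, 3))
                remaining -= 3
            else:
                plants.append((2, 2))
                remaining -= 2
    else:
        while remaining:
            plants.append((1, 1))
            remaining -= 1

    patients = planter.eligible_patients(nrule)
    if len(patients) < len(plants):
        raise PlantingError(
            f"{nrule.rule_id}: only {len(patients)} eligible patients for "
            f"{len(plants)} plants"
        )
    for pid, (kind, _nflags) in zip(patients, plants):
        base = planter.by_patient[pid][0]
        d0 = min(start + datetime.timedelta(days=int(planter.rng.integers(0, 200))), end)

        def mk(code: str, d: datetime.date) -> ClaimRecord:
            return ClaimRecord(
                claim_id=planter.next_id(), patient_id=pid,
                provider_id=base.provider_id, service_date=d,
                procedure_code=code, units=1, billed_amount=110.0,
                birth_date=base.birth_date, place_of_service=base.place_of_service,
            )

        if kind == 1:  # cross-day: later claim flagged
            gap = max(1, min(window - 1, 1)) if window is not None else 1
            a, b = mk(c1, d0), mk(c2, min(d0 + datetime.timedelta(days=gap), end))
            planter.insert(nrule, [a, b], [b.claim_id])
        elif kind == 2:  # same-day pair: both flagged
            a, b = mk(c1, d0), mk(c2, d0)
            planter.insert(nrule, [a, b], [a.claim_id, b.claim_id])
        else:  # same-day triple: all three flagged
            a, b, c = mk(c1, d0), mk(c2, d0), mk(c2, d0)
            planter.insert(nrule, [a, b, c], [a.claim_id, b.claim_id, c.claim_id])


def _plant_noncoverage(
    planter: _Planter,
    nrule: NormalizedRule,
    count: int,
    date_range: tuple[datetime.date, datetime.date],
) -> None:
    if not nrule.excluded_scope:
        raise PlantingError(f"{nrule.rule_id}: no excluded service to plant")
    code = sorted(nrule.excluded_scope)[0]
    lo, hi = nrule.age_bounds
    start, end = date_range
    planted = 0
    for pid in planter.eligible_patients(nrule):
        if planted >= count:
            break
        base = planter.by_patient[pid][0]
        # find a service date at which the patient's age satisfies the bounds
        date = None
        for probe in range(0, (end - start).days + 1, 37):
            d = start + datetime.timedelta(days=probe)
            from .engine import age_in_years

            a = age_in_years(base.birth_date, d)
            if (lo is None or a >= lo) and (hi is None or a <= hi):
                date = d
                break
        if date is None:
            continue
        claim = ClaimRecord(
            claim_id=planter.next_id(), patient_id=pid, provider_id=base.provider_id,
            service_date=date, procedure_code=code, units=1, billed_amount=95.0,
            birth_date=base.birth_date, place_of_service=base.place_of_service,
        )
        planter.insert(nrule, [claim], [claim.claim_id])
        planted += 1
    if planted < count:
        raise PlantingError(
            f"{nrule.rule_id}: no eligible patient window for "
            f"{count - planted} of {count} plants"
        )


def plant_violations(
    db: ClaimsDB,
    rules: list[NormalizedRule],
    plan: tuple[tuple[str, int], ...],
    seed: int,
    date_range: tuple[datetime.date, datetime.date] | None = None,
) -> LabelledClaimsDB:
    """Insert controlled violations into a clean background database."""
    rng = np.random.default_rng(seed)
    by_id = {r.rule_id: r for r in rules}
    planter = _Planter(db, rules, rng)
    if date_range is None:
        dates = [c.service_date for c in db] or [datetime.date(2019, 1, 1)]
        date_range = (min(dates), max(dates))
    for rule_id, count in plan:
        if count == 0:
            continue
        nrule = by_id.get(rule_id)
        if nrule is None:
            raise PlantingError(f"plan references unknown rule {rule_id!r}")
        if nrule.rule_type == "service_limitation":
            _plant_limitation(planter, nrule, count, date_range)
        elif nrule.rule_type == "mutual_exclusion":
            _plant_exclusion(planter, nrule, count, date_range)
        else:
            _plant_noncoverage(planter, nrule, count, date_range)
    return LabelledClaimsDB(
        claims=ClaimsDB(planter.records), planted=frozenset(planter.planted)
    )


def generate_dataset(
    config: SyntheticConfig | None = None,
    rules: RuleSet | list[NormalizedRule] | None = None,
) -> LabelledClaimsDB:
    """Clean background plus planted violations, deterministic per seed."""
    config = config or SyntheticConfig()
    if rules is None:
        rules = example_rules()
    if isinstance(rules, RuleSet):
        nrules = [normalize(r) for r in rules]
    else:
        nrules = list(rules)
    background = generate_background(config, nrules)
    return plant_violations(
        background,
        nrules,
        config.violations_to_plant,
        seed=config.seed + 1,
        date_range=config.date_range,
    )
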