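import datetime

import pytest

from claimrules import (
    ClaimRecord,
    Condition,
    EvaluationContext,
    Rule,
    RuleSource,
    builtin_ontology,
    example_rules,
    normalize,
)


@pytest.fixture(scope="session")
def ontology():
    return builtin_ontology()


@pytest.fixture(scope="session")
def rules():
    return example_rules()


@pytest.fixture(scope="session")
def normalized_rules(rules):
    return [normalize(r) for r in rules]


@pytest.fixture
def claim_factory():
    """Build claims with terse arguments: day offsets instead of dates."""
    counter = {"n": 0}

    def make(
        code="D0120",
        day=0,
        units=1,
        amount=100.0,
        patient="P1",
        provider="PR1",
        birth=datetime.date(1990, 6, 15),
        claim_id=None,
    ):
        counter["n"] += 1
        return ClaimRecord(
            claim_id=claim_id or f"c{counter['n']:03d}",
            patient_id=patient,
            provider_id=provider,
            service_date=datetime.date(2020, 1, 1) + datetime.timedelta(days=day),
            procedure_code=code,
            units=units,
            billed_amount=amount,
            birth_date=birth,
            place_of_service="11",
        )

    return make


@pytest.fixture
def context_factory(claim_factory):
    def make(*claims, patient="P1"):
        return EvaluationContext(patient_id=patient, claims=tuple(claims))

    return make


def make_rule(rule_id, conditions, rule_type="service_limitation",
              polarity="compliance", fragment="f1", document="doc", text=""):
    """Shorthand rule constructor used across test modules."""
    return Rule(
        id=rule_id,
        rule_type=rule_type,
        polarity=polarity,
        conditions=tuple(Condition(n, tuple(v)) for n, v in conditions),
        source=RuleSource(document=document, fragment=fragment, text=text),
    )
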