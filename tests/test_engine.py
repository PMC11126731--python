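"""Pipeline assembly, sliding windows, execution, and the brute-force oracle."""

import datetime
import itertools

import numpy as np
import pytest

from claimrules import (
    ClaimsDB,
    Condition,
    EvaluationContext,
    Rule,
    assemble_pipeline,
    brute_force_flags,
    execute_rules,
    normalize,
    run_pipeline,
    sliding_windows,
)
from claimrules.errors import ContextSizeError, ParameterError, SchemaError

from conftest import make_rule


def _nrule(conditions, rule_type="service_limitation", rule_id="r"):
    return normalize(
        make_rule(rule_id, conditions, rule_type=rule_type, polarity="non_compliance")
    )


LIMIT_D0145 = [
    ("hasApplicableService", ("D0145",)),
    ("hasMinUnits", (2,)),
    ("hasSlidingWindowInDays", (180,)),
]
EXCLUSION_PAIR = [
    ("hasApplicableService", ("D4355", "D1110")),
    ("hasSlidingWindowInDays", (1,)),
]


class TestAssemblePipeline:
    def test_limitation_pipeline_shape(self):
        pipe = assemble_pipeline(_nrule(LIMIT_D0145))
        kinds_ops = [(c.kind, c.op) for c in pipe.components]
        assert kinds_ops == [
            ("filter", "code_in"),
            ("splitter", "sliding_window"),
            ("evaluator", "cumulative_sum"),
        ]

    def test_exclusion_pipeline_shape(self):
        pipe = assemble_pipeline(_nrule(EXCLUSION_PAIR, rule_type="mutual_exclusion"))
        assert [(c.kind, c.op) for c in pipe.components] == [
            ("filter", "code_in"),
            ("splitter", "sliding_window"),
            ("evaluator", "co_occurrence"),
        ]

    def test_noncoverage_pipeline_shape(self):
        pipe = assemble_pipeline(
            _nrule(
                [("hasExcludedService", ("D9999",)), ("hasMaxAge", (20,))],
                rule_type="non_coverage",
            )
        )
        assert [(c.kind, c.op) for c in pipe.components] == [
            ("filter", "code_in"),
            ("filter", "age_le"),
            ("evaluator", "always_true"),
        ]


class TestSlidingWindows:
    def test_same_day_claims_share_windows(self, claim_factory, context_factory):
        ctx = context_factory(claim_factory(day=0), claim_factory(day=0))
        windows = list(sliding_windows(ctx, 1))
        assert len(windows) == 2
        assert all(len(w.claims) == 2 for w in windows)

    def test_trailing_windows_cover_strictly_less_than_span(
        self, claim_factory, context_factory
    ):
        ctx = context_factory(
            claim_factory(day=0, claim_id="a"),
            claim_factory(day=100, claim_id="b"),
            claim_factory(day=200, claim_id="c"),
        )
        windows = [
            tuple(c.claim_id for c in w.claims) for w in sliding_windows(ctx, 180)
        ]
        assert windows == [("a",), ("a", "b"), ("b", "c")]

    def test_single_claim_yields_singleton_window(self, claim_factory, context_factory):
        ctx = context_factory(claim_factory(day=5))
        assert [len(w.claims) for w in sliding_windows(ctx, 365)] == [1]

    def test_every_claim_anchors_exactly_one_window(self, claim_factory, context_factory):
        claims = [claim_factory(day=d) for d in (0, 3, 3, 10)]
        ctx = context_factory(*claims)
        assert len(list(sliding_windows(ctx, 7))) == len(claims)

    def test_nonpositive_window_rejected(self, claim_factory, context_factory):
        ctx = context_factory(claim_factory())
        with pytest.raises(ParameterError):
            list(sliding_windows(ctx, 0))


class TestRunPipeline:
    def test_single_claim_under_limit_not_flagged(self, claim_factory, context_factory):
        ctx = context_factory(claim_factory(code="D0145"))
        assert run_pipeline(assemble_pipeline(_nrule(LIMIT_D0145)), ctx) == []

    def test_second_claim_within_window_flagged_with_evidence(
        self, claim_factory, context_factory
    ):
        first = claim_factory(code="D0145", day=0)
        second = claim_factory(code="D0145", day=30)
        flags = run_pipeline(
            assemble_pipeline(_nrule(LIMIT_D0145)), context_factory(first, second)
        )
        assert [f.claim_id for f in flags] == [second.claim_id]
        assert flags[0].evidence["aggregate"] == 2
        assert flags[0].evidence["threshold"] == 2
        assert set(flags[0].triggering_claim_ids) == {first.claim_id, second.claim_id}

    def test_claims_outside_window_do_not_accumulate(self, claim_factory, context_factory):
        ctx = context_factory(
            claim_factory(code="D0145", day=0), claim_factory(code="D0145", day=200)
        )
        assert run_pipeline(assemble_pipeline(_nrule(LIMIT_D0145)), ctx) == []

    def test_units_contribute_their_count_not_one(self, claim_factory, context_factory):
        ctx = context_factory(claim_factory(code="D0145", units=2))
        flags = run_pipeline(assemble_pipeline(_nrule(LIMIT_D0145)), ctx)
        assert len(flags) == 1  # one claim with 2 units already exceeds "once"

    def test_same_day_exclusive_pair_flags_both(self, claim_factory, context_factory):
        a = claim_factory(code="D4355", day=5)
        b = claim_factory(code="D1110", day=5)
        pipe = assemble_pipeline(_nrule(EXCLUSION_PAIR, rule_type="mutual_exclusion"))
        flags = run_pipeline(pipe, context_factory(a, b))
        assert {f.claim_id for f in flags} == {a.claim_id, b.claim_id}

    def test_cross_day_pair_outside_one_day_window_is_compliant(
        self, claim_factory, context_factory
    ):
        a = claim_factory(code="D4355", day=5)
        b = claim_factory(code="D1110", day=6)
        pipe = assemble_pipeline(_nrule(EXCLUSION_PAIR, rule_type="mutual_exclusion"))
        assert run_pipeline(pipe, context_factory(a, b)) == []

    def test_inclusive_window_mode_extends_reach(self, claim_factory, context_factory):
        a = claim_factory(code="D4355", day=5)
        b = claim_factory(code="D1110", day=6)
        pipe = assemble_pipeline(_nrule(EXCLUSION_PAIR, rule_type="mutual_exclusion"))
        flags = run_pipeline(pipe, context_factory(a, b), window_mode="inclusive")
        assert [f.claim_id for f in flags] == [b.claim_id]  # later of the pair

    def test_age_filter_uses_completed_years(self, claim_factory, context_factory):
        nrule = _nrule(
            [("hasExcludedService", ("D9999",)), ("hasMaxAge", (2,))],
            rule_type="non_coverage",
        )
        pipe = assemble_pipeline(nrule)
        # service the day before the third birthday: age 2, still covered by the bound
        before = claim_factory(
            code="D9999", day=0, birth=datetime.date(2017, 1, 2), claim_id="young"
        )
        after = claim_factory(
            code="D9999", day=1, birth=datetime.date(2017, 1, 2), claim_id="three",
        )
        flags = run_pipeline(pipe, context_factory(before, after))
        assert [f.claim_id for f in flags] == ["young"]

    def test_group_by_provider_splits_accumulation(self, claim_factory, context_factory):
        nrule = _nrule(
            LIMIT_D0145 + [("hasBillingCommonality", ("same_provider",))]
        )
        same = context_factory(
            claim_factory(code="D0145", day=0, provider="PR1"),
            claim_factory(code="D0145", day=10, provider="PR2"),
        )
        assert run_pipeline(assemble_pipeline(nrule), same) == []


class TestExecuteRules:
    def test_empty_db_gives_empty_results(self, normalized_rules):
        assert execute_rules(normalized_rules, ClaimsDB([])) == []

    def test_unrelated_codes_are_filtered_out(self, claim_factory, normalized_rules):
        db = ClaimsDB([claim_factory(code="D7140", day=d) for d in range(5)])
        assert execute_rules(normalized_rules, db) == []

    def test_results_ordered_and_order_invariant(self, claim_factory):
        claims = [
            claim_factory(code="D0145", day=0, patient="P2"),
            claim_factory(code="D0145", day=30, patient="P2"),
            claim_factory(code="D4355", day=10, patient="P1"),
            claim_factory(code="D1110", day=10, patient="P1"),
        ]
        nrules = [
            _nrule(LIMIT_D0145, rule_id="lim"),
            _nrule(EXCLUSION_PAIR, rule_type="mutual_exclusion", rule_id="mex"),
        ]
        baseline = execute_rules(nrules, ClaimsDB(claims))
        assert baseline == sorted(
            baseline, key=lambda f: (f.rule_id, f.patient_id, f.claim_id)
        )
        assert len(baseline) == 3  # one excess claim + both of the same-day pair
        for perm in itertools.permutations(claims):
            assert execute_rules(nrules, ClaimsDB(list(perm))) == baseline

    def test_schema_violation_names_record(self, claim_factory):
        with pytest.raises(SchemaError, match="c9"):
            ClaimsDB.from_records(
                [
                    {
                        "claim_id": "c9",
                        "patient_id": "P1",
                        "provider_id": "PR1",
                        "service_date": "2020-13-45",
                        "procedure_code": "D0120",
                        "units": 1,
                        "billed_amount": 10.0,
                        "birth_date": "1990-01-01",
                    }
                ]
            )

    def test_csv_round_trip(self, claim_factory, tmp_path):
        db = ClaimsDB([claim_factory(day=d) for d in range(4)])
        path = tmp_path / "claims.csv"
        db.to_csv(path)
        again = ClaimsDB.from_csv(path)
        assert len(again) == len(db)
        assert {c.claim_id for c in again} == {c.claim_id for c in db}


# -- oracle equivalence ----------------------------------------------------


def _random_instance(rng, claim_factory):
    n = int(rng.integers(1, 13))
    codes = ["D0145", "D1110", "D4355", "D0120"]
    claims = [
        claim_factory(
            code=str(rng.choice(codes)),
            day=int(rng.integers(0, 400)),
            units=int(rng.integers(0, 3)),
            amount=float(rng.integers(10, 300)),
            provider=f"PR{int(rng.integers(1, 3))}",
            birth=datetime.date(int(rng.integers(1950, 2019)), 6, 15),
        )
        for _ in range(n)
    ]
    kind = int(rng.integers(0, 3))
    window = int(rng.integers(1, 250))
    if kind == 0:
        conds = [
            ("hasApplicableService", tuple(sorted(set(
                str(c) for c in rng.choice(codes, size=int(rng.integers(1, 3)))
            )))),
            ("hasMinUnits", (int(rng.integers(1, 4)),)),
        ]
        if rng.random() < 0.8:
            conds.append(("hasSlidingWindowInDays", (window,)))
        if rng.random() < 0.3:
            conds.append(("hasBillingCommonality", ("same_provider",)))
        nrule = _nrule(conds)
    elif kind == 1:
        conds = [("hasApplicableService", ("D4355", "D1110"))]
        if rng.random() < 0.8:
            conds.append(("hasSlidingWindowInDays", (window,)))
        nrule = _nrule(conds, rule_type="mutual_exclusion")
    else:
        conds = [("hasExcludedService", ("D0120",)), ("hasMaxAge", (int(rng.integers(2, 70)),))]
        nrule = _nrule(conds, rule_type="non_coverage")
    return nrule, EvaluationContext("P1", tuple(claims))


class TestOracleEquivalence:
    def test_pipeline_matches_brute_force_on_random_instances(self, claim_factory):
        rng = np.random.default_rng(2024)
        for _ in range(250):
            nrule, ctx = _random_instance(rng, claim_factory)
            pipeline_flags = {
                f.claim_id for f in run_pipeline(assemble_pipeline(nrule), ctx)
            }
            assert pipeline_flags == brute_force_flags(nrule, ctx)

    def test_empty_context_gives_empty_set(self):
        nrule = _nrule(LIMIT_D0145)
        assert brute_force_flags(nrule, EvaluationContext("P1", ())) == set()

    def test_single_claim_cannot_be_mutually_exclusive(self, claim_factory, context_factory):
        nrule = _nrule(EXCLUSION_PAIR, rule_type="mutual_exclusion")
        ctx = context_factory(claim_factory(code="D4355"))
        assert brute_force_flags(nrule, ctx) == set()

    def test_size_guard(self, claim_factory, context_factory):
        ctx = context_factory(*[claim_factory(day=d) for d in range(25)])
        with pytest.raises(ContextSizeError):
            brute_force_flags(_nrule(LIMIT_D0145), ctx)


class TestEngineProperties:
    def test_enlarging_window_never_unflags(self, claim_factory):
        rng = np.random.default_rng(7)
        for _ in range(40):
            claims = [
                claim_factory(code="D0145", day=int(rng.integers(0, 300)))
                for _ in range(int(rng.integers(2, 8)))
            ]
            ctx = EvaluationContext("P1", tuple(claims))
            w1, w2 = sorted(rng.integers(1, 250, size=2))
            flags = {}
            for w in (int(w1), int(w2)):
                nrule = _nrule(
                    [("hasApplicableService", ("D0145",)), ("hasMinUnits", (2,)),
                     ("hasSlidingWindowInDays", (w,))]
                )
                flags[w] = {f.claim_id for f in run_pipeline(assemble_pipeline(nrule), ctx)}
            assert flags[int(w1)] <= flags[int(w2)]

    def test_filters_commute(self, claim_factory):
        nrule = _nrule(
            [("hasExcludedService", ("D9999",)), ("hasMinAge", (5,)), ("hasMaxAge", (20,))],
            rule_type="non_coverage",
        )
        pipe = assemble_pipeline(nrule)
        claims = [
            claim_factory(code=c, birth=datetime.date(y, 1, 1))
            for c, y in [("D9999", 2010), ("D9999", 1960), ("D0120", 2010)]
        ]
        from claimrules.engine import _apply_filter

        for perm in itertools.permutations(pipe.filters):
            survivors = [
                c.claim_id for c in claims if all(_apply_filter(f, c) for f in perm)
            ]
            assert survivors == [claims[0].claim_id]

    def test_inversion_complementarity(self, claim_factory):
        # histories compliant with "at most k units per window" are never
        # flagged by the inverted ">= k+1 units" rule, and violating
        # histories always are
        rng = np.random.default_rng(11)
        k, window = 2, 90
        nrule = _nrule(
            [("hasApplicableService", ("D0145",)), ("hasMinUnits", (k + 1,)),
             ("hasSlidingWindowInDays", (window,))]
        )
        pipe = assemble_pipeline(nrule)
        for _ in range(60):
            claims = [
                claim_factory(code="D0145", day=int(rng.integers(0, 250)), units=1)
                for _ in range(int(rng.integers(1, 7)))
            ]
            ctx = EvaluationContext("P1", tuple(claims))
            ordered = sorted(claims, key=lambda c: c.sort_key)
            worst = max(
                sum(
                    1
                    for c in ordered
                    if 0 <= (anchor.service_date - c.service_date).days < window
                    and c.sort_key <= anchor.sort_key
                )
                for anchor in ordered
            )
            flagged = run_pipeline(pipe, ctx)
            assert bool(flagged) == (worst > k)
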