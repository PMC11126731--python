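# Methods

This note records the model behind `claimrules`, the conventions the
implementation fixes where several were defensible, and what the test
suite does and does not demonstrate.

## Rule model and ontology constraints

A rule is a conjunction of conditions; each condition is a property from
a condition vocabulary ("ontology-lite") with a value set read as a
disjunction. The vocabulary declares per property: the value kind
(numeric, duration amount/unit, code set, categorical), the maximum
number of conditions of that property per rule, whether the property is
an upper or lower bound, and pairwise disjointness (a procedure code may
not appear under both `hasApplicableService` and `hasExcludedService` in
one rule). Numeric and duration-amount properties are single-valued by
construction.

Validation returns violations as data rather than raising: the intended
workflow is human curation of imperfect rules, so a rule that breaks a
cardinality or disjointness constraint is surfaced (and quarantined in
`RuleSet.rejected` at parse time), never silently dropped.

Rules serialize to RDF Turtle/N-Triples (each rule a tree: rule root,
condition vertices, value leaves) and to a JSON dialect that is easier
to hand-author in tests. RDF is a set of triples, so serialization
preserves value *sets* but not value *order*; round-trips are exact up
to ordering. Vocabulary drift between singular and plural surface forms
(`hasMinUnit` vs `hasMinUnits`) is canonicalized to the plural via an
alias table.

## Similarity metrics

* Condition similarity: `1/(1+|v_x−v_y|)` when the property is numeric
  and single-valued in both rules; otherwise the Jaccard — or, in `dice`
  mode, Sørensen–Dice — overlap of the value sets; 0 when the condition
  is absent from either rule. A numeric condition that (illegally)
  carries several values falls back to the set branch on stringified
  values, since the numeric branch is defined only for singletons.
* Structure similarity: the same overlap applied to condition-name sets,
  ignoring values. Two condition-less rules score 1 (vacuous identity,
  consistent with self-similarity in the limit).
* Overall rule similarity: the arithmetic mean of the structure
  similarity and the condition similarities of every condition appearing
  in either rule, i.e. divided by `1 + |union|`.
* Text similarity: angular similarity `1 − arccos(cos)/π` between text
  embeddings, with the cosine clamped to [−1, 1] before the arccos. The
  default embedder is a deterministic seeded character-trigram hashing
  embedder (256 buckets, signed counts): it needs no model download and
  makes S_T reproducible; any object with an `embed(str) -> vector`
  method (e.g. a sentence-transformer wrapper) can be substituted. The
  formula, not a particular embedding model, is the contract; absolute
  S_T values from different embedders are not comparable.

Since Dice = 2J/(1+J) is monotone in Jaccard and ≥ J, every set-overlap
quantity in `dice` mode dominates its `jaccard` counterpart; this is
property-tested.

Rule-set matching uses a partial-match intersection: a ground-truth and
an extracted rule are candidates when they share (document, fragment)
provenance and at least one condition name with overlapping value sets
(numeric values overlap iff equal). The definition does not say how
many-to-many candidates resolve; the implementation fixes a one-to-one
greedy matching by descending overall similarity with lexicographic id
tie-breaks, so the matched-pair count is a single well-defined numerator
for both precision (over extracted) and recall (over ground truth). Both
sets empty scores all metrics 1; an empty extracted set against a
non-empty ground truth scores 0.

Pairwise rule-set summaries report median and IQR over all n(n−1)/2
distinct unordered pairs; quantiles use linear interpolation (NumPy
default, type 7). A convention had to be fixed; nothing downstream is
sensitive to the choice at the reported precision.

## Normalization

Execution flags violations, so compliance rules are inverted first:
`hasMaxUnits(k)` → `hasMinUnits(k+1)` (the first excess unit is the
(k+1)-th), and `hasMaxAmount(a)` → `hasMinAmount(a)` with an *exclusive*
comparison (total > a). The exclusive bound avoids inventing a currency
granularity (a + 0.01 would presume cents). Non-compliance rules pass
through unchanged, making normalization idempotent.

Temporal pairs consolidate with day = 1, week = 7, month = 30,
year = 365: the six-month example fixes month at 30 days (6 × 30 = 180),
and 365 keeps year arithmetic deterministic without calendar logic.
Calendar-aware semantics (anniversary dates, leap years) are explicitly
out of scope.

Field binding resolves each condition against a configurable field map
(YAML-overridable; the bundled default maps onto the standard claims
schema: procedure_code, service_date, units, billed_amount, provider_id,
patient_id, birth_date, place_of_service).
`hasBillingCommonality(same_provider)` contributes `provider_id` as a
group-by key. An unmapped condition is a hard error naming the gap — the
workflow surfaces it to an analyst rather than guessing.

## Execution semantics

The evaluation context is one patient's claims in chronological order,
ties broken by claim id. Windows are *trailing*, anchored at each claim:
the anchor's window holds every claim dated within `window_days` before
it (strictly fewer days, so a 1-day window means same calendar day; an
`inclusive` mode using ≤ is available as a config switch). Anchored
trailing windows are equivalent to enumerating all maximal
sub-sequences for threshold detection, run in linear scans, and give
every flag a unique triggering context.

The cumulative-sum evaluator totals units (a claim with u units
contributes u) or billed amount over the window claims up to and
including the anchor — same-day claims sorted after the anchor do not
count toward its total — and flags the anchor when the total reaches the
inverted threshold. Consequently only excess claims are flagged, never
the initial legitimate ones; investigators see the billing event that
crossed the limit. Whether a real adjudication system flags only excess
claims or the whole violating window is not publicly documented; this
positional convention is the package's choice and is applied
consistently by engine, oracle, and generator.

The co-occurrence evaluator flags the anchor when a different code of
the exclusive pair occurs in its window: the later claim of a cross-day
pair is flagged, and a same-day pair flags both claims (each is in the
other's window). Age filters use completed years at service date with
inclusive bounds, so "under three years of age" is `hasMaxAge(2)` — the
curated semantics, since extracting `hasMaxAge(3)` from that phrase is a
known failure mode worth modelling correctly.

Patients are evaluated independently and results are sorted by (rule,
patient, claim); any parallel or shuffled execution order yields an
identical flag set. No distributed runtime is included — independence is
the contract that would make one safe.

`brute_force_flags` is an independent oracle: it enumerates claim
subsets (service limitations), ordered claim pairs (mutual exclusions),
or filtered claims (non-coverage) and applies the rule predicate
directly, sharing no code with the pipeline path. It is exponential in
context size and guarded at 20 claims. Pipeline/oracle agreement is
asserted exactly on hundreds of randomized instances per run.

## Synthetic data generator

The generator emulates a desk-scale claims database: by default 1,000
patients, two years of service dates, 2–8 claims per patient, CDT-style
dental procedure codes (D0120, D0145, D1110, D4355, … plus filler
codes), one or two providers per patient, unit counts of 1, and billed
amounts of 40–260 currency units. The defaults, chosen once, include 66
planted violations (30 service-limitation, 20 mutual-exclusion, 16
non-coverage), sized so the planted-recovery check runs in seconds on
one CPU.

The background is *constructed* clean rather than sampled and filtered:
each candidate claim is checked against every rule before placement
(using a conservative neighbourhood bound on window totals — any window
containing the candidate lies within one window-length of it) and falls
back to an unconstrained filler code when a placement would violate; the
finished background is then verified with the engine. This makes label
completeness provable rather than probabilistic. Violations are planted
on patients with no claims touching the target rule's scope, so plants
cannot interact with the background or each other; the recorded labels
are exactly the claims the engine's anchor convention flags (the excess
claim of a limitation plant, both claims of a same-day exclusive pair,
the non-covered claim). A same-day pair under a 1-day window always
flags both anchors, so an exclusion plant count of exactly 1 is
unsatisfiable and raises a planting error; odd counts are met with a
same-day triple (3 flags).

What passing on this data shows: the engine implements its stated
semantics exactly, end to end, at realistic scale. What it does not
show: performance on real claims feeds, whose code frequencies, payer
mix, units distributions, data-entry errors, and rule interactions the
generator deliberately does not model.

## Numerical and degenerate-input conventions

* Zero denominators in precision/recall/F1 yield 0 for the affected
  metric (all three are 1 only in the doubly-empty matching case).
* Numeric condition values compare on the number line (1 ≡ 1.0); value
  sets compare on a canonical string form.
* Flags, reports, and serialized rule sets are byte-stable for fixed
  inputs; generation is deterministic per seed.
* Estimated value in reports sums billed amounts over *distinct* flagged
  claims (a claim flagged by several rules counts once); whether a real
  deployment would sum billed or paid amounts is unknowable from public
  material — billed is the package's choice.
* Explanations render the exclusive pair in the order the rule declares
  it; rules re-read from RDF carry set order (alphabetical), since RDF
  does not preserve value order.

## Known limitations

* No NLP extraction of rules from policy text; rules are authored,
  loaded from files, or generated.
* No OWL reasoning or SHACL beyond the listed constraint kinds.
* Month/year day-counts are fixed conventions, not calendar arithmetic.
* The hashing embedder is a determinism device, not a semantic model;
  use a sentence-embedding backend for meaningful S_T on real policy
  text.
* Problem sizes in tests and the acceptance script (1,000 patients,
  250 oracle instances, ≤ 12 claims per oracle context) are the
  package's chosen desk-scale study conditions.
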