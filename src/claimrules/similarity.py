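"""Rule similarity metrics and precision/recall evaluation.

Four metrics compare rules:

* condition similarity ``S_C`` — per condition property: for a numeric
  condition present in both rules with single values ``v_x``, ``v_y`` it
  is ``1 / (1 + |v_x - v_y|)``; for a non-numeric condition present in
  both it is the Jaccard (or Sørensen–Dice) overlap of the value sets;
  it is 0 when the condition is missing from either rule.
* structure similarity ``S_S`` — Jaccard (or Dice) overlap of the two
  rules' condition-name sets, ignoring values.
* overall rule similarity ``S_R`` — the arithmetic mean of ``S_S`` and
  the ``S_C`` of every condition in either rule:
  ``S_R = (S_S + sum S_C) / (1 + |C(R_x) ∪ C(R_y)|)``.
* text similarity ``S_T`` — angular similarity of text embeddings:
  ``1 - arccos(cos(u_x, u_y)) / pi``.

Rule-set evaluation uses a partial-match intersection: an extracted rule
matches a ground-truth rule when both originate from the same document
fragment and share at least one condition with overlapping values.  The
matching is resolved one-to-one, greedily by descending ``S_R``, so the
matched-pair count serves as a single numerator for both precision
(``|matched| / |E|``) and recall (``|matched| / |G|``).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .embedding import HashingEmbedder
from .errors import DegenerateEmbeddingError, InsufficientDataError, ProvenanceError
from .model import Rule, RuleSet
from .ontology import Ontology, builtin_ontology, canonical_name

__all__ = [
    "condition_similarity",
    "structure_similarity",
    "rule_similarity",
    "text_similarity",
    "match_rules",
    "classification_prf",
    "pairwise_similarity_summary",
    "SimilarityReport",
    "MatchReport",
    "ClassificationCounts",
    "PairwiseSummary",
]

MODES = ("jaccard", "dice")


def _check_mode(mode: str) -> None:
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")


def _set_overlap(a: frozenset, b: frozenset, mode: str) -> float:
    if not a and not b:
        return 1.0
    inter = len(a & b)
    if mode == "dice":
        return 2.0 * inter / (len(a) + len(b))
    return inter / len(a | b)


def _as_number(v) -> float | None:
    if isinstance(v, bool):
        return None
    if isinstance(v, (int, float)):
        return float(v)
    try:
        return float(v)
    except (TypeError, ValueError):
        return None


def condition_similarity(
    cond_name: str,
    rule_x: Rule,
    rule_y: Rule,
    mode: str = "jaccard",
    ontology: Ontology | None = None,
) -> float:
    """``S_C`` for one condition property across two rules."""
    _check_mode(mode)
    ontology = ontology or builtin_ontology()
    name = canonical_name(cond_name)
    cdef = ontology.get(name)
    if cdef is None:
        raise KeyError(f"unknown condition property {cond_name!r}")
    cx = rule_x.conditions_named(name)
    cy = rule_y.conditions_named(name)
    if not cx or not cy:
        return 0.0
    if cdef.is_numeric and len(cx) == 1 and len(cy) == 1:
        vx, vy = cx[0].values, cy[0].values
        if len(vx) == 1 and len(vy) == 1:
            nx, ny = _as_number(vx[0]), _as_number(vy[0])
            if nx is not None and ny is not None:
                return 1.0 / (1.0 + abs(nx - ny))
    # Non-numeric (or multi-valued numeric): set overlap of values.
    sx = frozenset().union(*(c.value_set() for c in cx))
    sy = frozenset().union(*(c.value_set() for c in cy))
    return _set_overlap(sx, sy, mode)


def structure_similarity(rule_x: Rule, rule_y: Rule, mode: str = "jaccard") -> float:
    """``S_S``: overlap of the two rules' condition-name sets (values ignored).

    Two empty rules are defined maximally similar (vacuous identity)."""
    _check_mode(mode)
    return _set_overlap(rule_x.condition_names(), rule_y.condition_names(), mode)


@dataclass(frozen=True)
class SimilarityReport:
    """Per-condition, structure, overall (and optionally text) similarity."""

    per_condition: dict[str, float]
    structure: float
    overall: float
    mode: str
    text: float | None = None

    @property
    def mean_condition(self) -> float:
        """Average ``S_C`` over the union of condition names (0 if no conditions)."""
        if not self.per_condition:
            return 0.0
        return sum(self.per_condition.values()) / len(self.per_condition)


def rule_similarity(
    rule_x: Rule,
    rule_y: Rule,
    mode: str = "jaccard",
    ontology: Ontology | None = None,
) -> SimilarityReport:
    """``S_R``: mean of structure similarity and every condition similarity."""
    _check_mode(mode)
    ontology = ontology or builtin_ontology()
    union = sorted(rule_x.condition_names() | rule_y.condition_names())
    per = {
        name: condition_similarity(name, rule_x, rule_y, mode, ontology)
        for name in union
    }
    s_s = structure_similarity(rule_x, rule_y, mode)
    overall = (s_s + sum(per.values())) / (1 + len(union))
    return SimilarityReport(per_condition=per, structure=s_s, overall=overall, mode=mode)


def text_similarity(text_x: str, text_y: str, embedder=None) -> float:
    """``S_T``: angular similarity between the embeddings of two texts.

    The cosine is clamped to [-1, 1] before the arccos, so floating-point
    noise cannot push the result outside [0, 1].
    """
    embedder = embedder or HashingEmbedder()
    ux = np.asarray(embedder.embed(text_x), dtype=float)
    uy = np.asarray(embedder.embed(text_y), dtype=float)
    nx, ny = np.linalg.norm(ux), np.linalg.norm(uy)
    if nx == 0.0 or ny == 0.0:
        raise DegenerateEmbeddingError("embedder returned a zero-norm vector")
    cos = float(np.clip(ux @ uy / (nx * ny), -1.0, 1.0))
    return 1.0 - float(np.arccos(cos)) / np.pi


# ------------------------------------------------------------ matching


@dataclass(frozen=True)
class MatchReport:
    """Outcome of partial-match evaluation of an extracted rule set
    against a ground-truth rule set."""

    matched_pairs: tuple[tuple[str, str, float], ...]  # (gt id, ex id, S_R)
    unmatched_gt: tuple[str, ...]
    unmatched_ex: tuple[str, ...]
    precision: float
    recall: float
    f1: float


def _values_overlap(gt: Rule, ex: Rule) -> bool:
    """Some condition name present in both rules with overlapping values
    (numeric values overlap iff equal, which set equality on the
    canonical string form gives us)."""
    for name in gt.condition_names() & ex.condition_names():
        if gt.values_of(name) & ex.values_of(name):
            return True
    return False


def match_rules(
    gt: RuleSet,
    ex: RuleSet,
    mode: str = "dice",
    ontology: Ontology | None = None,
) -> MatchReport:
    """Partial-match intersection of ground-truth and extracted rules.

    Candidates share a (document, fragment) provenance and at least one
    condition with overlapping values; candidates are resolved to a
    one-to-one matching greedily by descending ``S_R`` (ties broken by
    lexicographic id pair).
    """
    _check_mode(mode)
    ontology = ontology or builtin_ontology()
    if len(gt) == 0 and len(ex) == 0:
        return MatchReport((), (), (), 1.0, 1.0, 1.0)

    for rs in (gt, ex):
        for rule in rs:
            if rule.source is None:
                raise ProvenanceError(
                    f"rule {rule.id!r} lacks source provenance required for matching"
                )

    candidates = []
    for g in gt:
        for e in ex:
            if (g.source.document, g.source.fragment) != (
                e.source.document,
                e.source.fragment,
            ):
                continue
            if not _values_overlap(g, e):
                continue
            s_r = rule_similarity(g, e, mode, ontology).overall
            candidates.append((g.id, e.id, s_r))
    candidates.sort(key=lambda t: (-t[2], t[0], t[1]))

    used_gt: set[str] = set()
    used_ex: set[str] = set()
    matched = []
    for gid, eid, s_r in candidates:
        if gid in used_gt or eid in used_ex:
            continue
        matched.append((gid, eid, s_r))
        used_gt.add(gid)
        used_ex.add(eid)

    precision = len(matched) / len(ex) if len(ex) else 0.0
    recall = len(matched) / len(gt) if len(gt) else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return MatchReport(
        matched_pairs=tuple(matched),
        unmatched_gt=tuple(i for i in gt.ids if i not in used_gt),
        unmatched_ex=tuple(i for i in ex.ids if i not in used_ex),
        precision=precision,
        recall=recall,
        f1=f1,
    )


@dataclass(frozen=True)
class ClassificationCounts:
    """Exact tallies of a labelled claim classification."""

    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("classification counts must be non-negative")


def classification_prf(counts: ClassificationCounts) -> tuple[float, float, float]:
    """Precision ``tp/(tp+fp)``, recall ``tp/(tp+fn)`` and their harmonic
    mean; a zero denominator yields 0 for the affected metric."""
    tp, fp, fn = counts.tp, counts.fp, counts.fn
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f1


# --------------------------------------------------- pairwise summary


@dataclass(frozen=True)
class PairwiseSummary:
    """Median and IQR of the four metrics over all distinct unordered rule pairs."""

    n_pairs: int
    text: dict[str, float] = field(default_factory=dict)
    structure: dict[str, float] = field(default_factory=dict)
    mean_condition: dict[str, float] = field(default_factory=dict)
    overall: dict[str, float] = field(default_factory=dict)


def _median_iqr(values: list[float]) -> dict[str, float]:
    arr = np.asarray(values, dtype=float)
    q1, med, q3 = np.percentile(arr, [25, 50, 75])  # linear interpolation
    return {"median": float(med), "q1": float(q1), "q3": float(q3)}


def pairwise_similarity_summary(
    rules: RuleSet,
    embedder=None,
    mode: str = "jaccard",
    ontology: Ontology | None = None,
) -> PairwiseSummary:
    """Summarize rule diversity over all ``n(n-1)/2`` distinct pairs."""
    _check_mode(mode)
    if len(rules) < 2:
        raise InsufficientDataError("pairwise summary needs at least two rules")
    embedder = embedder or HashingEmbedder()
    ontology = ontology or builtin_ontology()

    texts, structs, conds, overalls = [], [], [], []
    ordered = sorted(rules, key=lambda r: r.id)
    for rx, ry in itertools.combinations(ordered, 2):
        rep = rule_similarity(rx, ry, mode, ontology)
        structs.append(rep.structure)
        conds.append(rep.mean_condition)
        overalls.append(rep.overall)
        tx = rx.source.text if rx.source else ""
        ty = ry.source.text if ry.source else ""
        texts.append(text_similarity(tx, ty, embedder))
    return PairwiseSummary(
        n_pairs=len(overalls),
        text=_median_iqr(texts),
        structure=_median_iqr(structs),
        mean_condition=_median_iqr(conds),
        overall=_median_iqr(overalls),
    )
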