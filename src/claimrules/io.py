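"""Reading and writing rule sets.

Two on-disk forms are supported:

* RDF Turtle / N-Triples — the interchange format for rule knowledge
  graphs.  Each rule is a ``cr:Rule`` node linked via ``cr:hasCondition``
  to condition nodes, whose leaves are the condition values; the encoding
  is a tree (rule root, condition vertices, value leaves).
* A JSON dialect — convenient for hand-authoring and for tests:
  ``{"role": ..., "rules": [{"id", "rule_type", "polarity",
  "source": {"document", "fragment", "text"},
  "conditions": [{"name", "values": [...]}]}]}``.

Rules that parse but break ontology constraints (cardinality,
disjointness, numeric arity) land in ``RuleSet.rejected`` rather than
aborting the load: imperfect rules are expected and get curated by a
human, not silently dropped.
"""

from __future__ import annotations

import decimal
import json
from pathlib import Path

import rdflib
from rdflib.namespace import RDF

from .errors import RuleFormatError, RuleStructureError, UnknownPropertyError
from .model import Condition, Rule, RuleSet, RuleSource, Scalar, validate_rule
from .ontology import CR, Ontology, canonical_name

__all__ = ["parse_rules", "serialize_rules", "write_rules"]

_HARD_KINDS = {"cardinality", "disjointness", "arity"}


def parse_rules(path: str | Path, ontology: Ontology) -> RuleSet:
    """Parse a rule file (Turtle, N-Triples, or the JSON dialect).

    Returns a :class:`RuleSet`; rules violating hard ontology constraints
    are collected in ``RuleSet.rejected`` together with their violations.
    """
    p = Path(path)
    if not p.exists():
        raise RuleFormatError(f"no such rule file: {p}")
    if p.suffix in {".ttl", ".nt"}:
        rules, role = _parse_rdf(p, ontology)
    else:
        rules, role = _parse_json(p.read_text(), str(p), ontology)

    accepted, rejected = [], []
    for rule in rules:
        hard = [v for v in validate_rule(rule, ontology) if v.kind in _HARD_KINDS]
        if hard:
            rejected.append((rule, hard))
        else:
            accepted.append(rule)
    return RuleSet(accepted, role=role, rejected=rejected)


def serialize_rules(rules: RuleSet, format: str = "turtle") -> str:
    """Serialize a rule set to Turtle or to the JSON dialect.

    ``parse_rules`` applied to the output reproduces the input up to
    condition/value ordering.
    """
    if format == "json":
        return _to_json(rules)
    if format in {"turtle", "ttl", "nt"}:
        return _to_rdf(rules, format="nt" if format == "nt" else "turtle")
    raise ValueError(f"unknown rule format {format!r}")


def write_rules(rules: RuleSet, path: str | Path, format: str | None = None) -> None:
    p = Path(path)
    if format is None:
        format = {".json": "json", ".nt": "nt"}.get(p.suffix, "turtle")
    p.write_text(serialize_rules(rules, format))


# ---------------------------------------------------------------- JSON


def _coerce_scalar(v) -> Scalar:
    if isinstance(v, bool) or not isinstance(v, (int, float, str)):
        raise RuleFormatError(f"unsupported condition value {v!r}")
    return v


def _parse_json(text: str, origin: str, ontology: Ontology) -> tuple[list[Rule], str]:
    try:
        raw = json.loads(text)
    except json.JSONDecodeError as exc:
        raise RuleFormatError(f"{origin}: line {exc.lineno}: {exc.msg}") from exc
    if isinstance(raw, list):
        raw = {"rules": raw}
    role = raw.get("role", "authored")
    rules = []
    for entry in raw.get("rules", []):
        try:
            conds = []
            for c in entry["conditions"]:
                name = canonical_name(c["name"])
                if name not in ontology:
                    raise UnknownPropertyError(
                        f"{origin}: rule {entry.get('id')!r} uses unknown "
                        f"condition property {c['name']!r}"
                    )
                conds.append(
                    Condition(
                        def_name=name,
                        values=tuple(_coerce_scalar(v) for v in c["values"]),
                        exclusive=bool(c.get("exclusive", False)),
                    )
                )
            src = entry.get("source")
            source = (
                RuleSource(src["document"], src["fragment"], src.get("text", ""))
                if src
                else None
            )
            rules.append(
                Rule(
                    id=str(entry["id"]),
                    rule_type=entry["rule_type"],
                    polarity=entry.get("polarity", "compliance"),
                    conditions=tuple(conds),
                    source=source,
                )
            )
        except KeyError as exc:
            raise RuleFormatError(f"{origin}: rule entry missing key {exc}") from exc
    return rules, role


def _to_json(rules: RuleSet) -> str:
    doc = {
        "role": rules.role,
        "rules": [
            {
                "id": r.id,
                "rule_type": r.rule_type,
                "polarity": r.polarity,
                **(
                    {
                        "source": {
                            "document": r.source.document,
                            "fragment": r.source.fragment,
                            "text": r.source.text,
                        }
                    }
                    if r.source
                    else {}
                ),
                "conditions": [
                    {
                        "name": c.def_name,
                        "values": list(c.values),
                        **({"exclusive": True} if c.exclusive else {}),
                    }
                    for c in r.conditions
                ],
            }
            for r in sorted(rules, key=lambda r: r.id)
        ],
    }
    return json.dumps(doc, indent=2, sort_keys=False) + "\n"


# ----------------------------------------------------------------- RDF


def _to_rdf(rules: RuleSet, format: str = "turtle") -> str:
    g = rdflib.Graph()
    g.bind("cr", CR)
    g.add((CR.ruleset, RDF.type, CR.RuleSet))
    g.add((CR.ruleset, CR.role, rdflib.Literal(rules.role)))
    for r in sorted(rules, key=lambda r: r.id):
        node = CR[f"rule-{r.id}"]
        g.add((CR.ruleset, CR.hasRule, node))
        g.add((node, RDF.type, CR.Rule))
        g.add((node, CR.ruleType, rdflib.Literal(r.rule_type)))
        g.add((node, CR.polarity, rdflib.Literal(r.polarity)))
        if r.source:
            g.add((node, CR.sourceDocument, rdflib.Literal(r.source.document)))
            g.add((node, CR.sourceFragment, rdflib.Literal(r.source.fragment)))
            if r.source.text:
                g.add((node, CR.sourceText, rdflib.Literal(r.source.text)))
        for i, c in enumerate(r.conditions):
            cnode = CR[f"rule-{r.id}-c{i}"]
            g.add((node, CR.hasCondition, cnode))
            g.add((cnode, RDF.type, CR.Condition))
            g.add((cnode, CR.property, CR[c.def_name]))
            if c.exclusive:
                g.add((cnode, CR.exclusive, rdflib.Literal(True)))
            for v in c.values:
                g.add((cnode, CR.hasValue, rdflib.Literal(v)))
    return g.serialize(format=format)


def _literal_value(lit) -> Scalar:
    v = lit.toPython()
    if isinstance(v, decimal.Decimal):
        return float(v)
    if isinstance(v, (int, float, str)):
        return v
    return str(v)


def _parse_rdf(path: Path, ontology: Ontology) -> tuple[list[Rule], str]:
    g = rdflib.Graph()
    fmt = "nt" if path.suffix == ".nt" else "turtle"
    try:
        g.parse(path, format=fmt)
    except Exception as exc:
        raise RuleFormatError(f"{path}: {exc}") from exc

    role_lit = next(g.objects(None, CR.role), None)
    role = str(role_lit) if role_lit is not None else "authored"

    rule_nodes = sorted(g.subjects(RDF.type, CR.Rule), key=str)
    _check_containment_tree(g, rule_nodes, path)

    rules = []
    for node in rule_nodes:
        rid = str(node).rsplit("#", 1)[-1]
        rid = rid[5:] if rid.startswith("rule-") else rid
        rtype = g.value(node, CR.ruleType)
        pol = g.value(node, CR.polarity)
        doc = g.value(node, CR.sourceDocument)
        frag = g.value(node, CR.sourceFragment)
        text = g.value(node, CR.sourceText)
        source = (
            RuleSource(str(doc), str(frag), str(text) if text is not None else "")
            if doc is not None and frag is not None
            else None
        )
        conds = []
        for cnode in sorted(g.objects(node, CR.hasCondition), key=str):
            prop = g.value(cnode, CR.property)
            if prop is None:
                raise RuleFormatError(f"{path}: condition {cnode} lacks cr:property")
            name = canonical_name(str(prop).rsplit("#", 1)[-1])
            if name not in ontology:
                raise UnknownPropertyError(
                    f"{path}: rule {rid!r} uses unknown condition property {name!r}"
                )
            values = tuple(
                _literal_value(v) for v in sorted(g.objects(cnode, CR.hasValue), key=str)
            )
            if not values:
                raise RuleFormatError(f"{path}: condition {name} in {rid!r} has no values")
            excl = g.value(cnode, CR.exclusive)
            conds.append(Condition(name, values, exclusive=bool(excl)))
        rules.append(
            Rule(
                id=rid,
                rule_type=str(rtype) if rtype is not None else "service_limitation",
                polarity=str(pol) if pol is not None else "compliance",
                conditions=tuple(conds),
                source=source,
            )
        )
    return rules, role


def _check_containment_tree(g: rdflib.Graph, rule_nodes, path: Path) -> None:
    """The rule/condition containment graph must be a forest: every
    condition node has exactly one parent rule and rule nodes are never
    nested under conditions (a cycle or sharing breaks the tree shape)."""
    rule_set = set(rule_nodes)
    parents: dict = {}
    for subj, obj in g.subject_objects(CR.hasCondition):
        if obj in rule_set:
            raise RuleStructureError(
                f"{path}: rule node {obj} appears as a condition of {subj}"
            )
        if obj in parents and parents[obj] != subj:
            raise RuleStructureError(
                f"{path}: condition node {obj} is shared between rules "
                f"{parents[obj]} and {subj}"
            )
        parents[obj] = subj
        if (obj, CR.hasCondition, None) in g:
            raise RuleStructureError(
                f"{path}: condition node {obj} has nested conditions"
            )
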