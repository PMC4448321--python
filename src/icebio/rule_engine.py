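"""Declarative forward-chaining over the triple graph.

A rule is a conjunctive body of triple patterns over variables and constants
plus a head of template triples. Head variables are either bound by the body
or minted deterministically from their mint directive (hash-based
skolemization — no blank nodes, ever), so re-running a rule on the same
bindings re-emits byte-identical triples. Batches of rules are applied
repeatedly until a fixpoint (an iteration that adds zero new triples), and
every emitted triple is tagged in a side index with the rule and binding that
produced it, which is what makes provenance dynamically re-derivable.

Rules only ever add triples; nothing is deleted (monotonicity), which is what
lets contradictory source assertions coexist as independent subclasses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple, Union

import yaml
from rdflib import Graph, Literal, URIRef
from rdflib.namespace import RDFS

from .namespaces import DENOTES, DENOTES_SUBCLASS_OF, MENTIONS, NAMESPACES, NamespaceTable
from .urimint import mint_bio_class_uri, mint_restriction_uri

Term = Union[URIRef, Literal, "Var"]
Triple = Tuple[Term, Term, Term]


class UnboundVariable(ValueError):
    """A head variable has neither a body binding nor a mint directive."""


class NonTermination(RuntimeError):
    """Fixpoint iteration exceeded the configured bound."""


@dataclass(frozen=True)
class Var:
    name: str

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"?{self.name}"


@dataclass(frozen=True)
class TransitivePredicate:
    """Reflexive-transitive closure over a base predicate (``rdfs:subClassOf*``)."""

    base: URIRef


def parse_term(token: str, namespaces: NamespaceTable = NAMESPACES) -> Term:
    if token.startswith("?"):
        return Var(token[1:])
    if token.startswith('"'):
        return Literal(token.strip('"'))
    if token.startswith(("http://", "https://")) or ":" in token:
        if token.endswith("*") and not token.startswith(("http://", "https://")):
            return TransitivePredicate(namespaces.expand(token[:-1]))
        return namespaces.expand(token)
    return Literal(token)


@dataclass(frozen=True)
class MintDirective:
    """How to skolemize one head variable.

    ``kind`` is ``restriction`` (components: property, filler) or ``bio-class``
    (components: a pattern tag followed by the defining inputs). Components may
    reference body variables (``?x``) or constants.
    """

    kind: str
    components: Tuple[str, ...]
    uri_prefix: str = "BIO_"

    def mint(self, binding: Mapping[str, Term], namespaces: NamespaceTable = NAMESPACES) -> URIRef:
        resolved: List[str] = []
        for c in self.components:
            if c.startswith("?"):
                name = c[1:]
                if name not in binding:
                    raise UnboundVariable(f"mint directive references unbound ?{name}")
                resolved.append(str(binding[name]))
            elif ":" in c or c.startswith("http"):
                resolved.append(str(namespaces.expand(c)))
            else:
                resolved.append(c)
        if self.kind == "restriction":
            if len(resolved) != 2:
                raise ValueError("restriction mint needs (property, filler)")
            return mint_restriction_uri(resolved[0], resolved[1])
        if self.kind == "bio-class":
            return mint_bio_class_uri(resolved[0], resolved[1:], uri_prefix=self.uri_prefix)
        raise ValueError(f"unknown mint kind {self.kind!r}")


@dataclass(frozen=True)
class Rule:
    name: str
    body: Tuple[Triple, ...]
    head: Tuple[Triple, ...]
    mint: Mapping[str, MintDirective] = field(default_factory=dict)
    record_vars: Tuple[str, ...] = ()
    mentions: Tuple[Tuple[str, str], ...] = ()  # (record var, minted/bound concept var)

    def __post_init__(self) -> None:
        body_vars = {t.name for pat in self.body for t in pat if isinstance(t, Var)}
        for pat in self.head:
            for t in pat:
                if isinstance(t, Var) and t.name not in body_vars and t.name not in self.mint:
                    raise UnboundVariable(f"rule {self.name}: head variable ?{t.name} is unbound")


@dataclass
class RuleBatch:
    label: str
    rules: Tuple[Rule, ...]

    def __post_init__(self) -> None:
        names = [r.name for r in self.rules]
        if len(names) != len(set(names)):
            raise ValueError(f"duplicate rule names in batch {self.label!r}")


@dataclass(frozen=True)
class DerivationRecord:
    """Provenance of one emitted triple: the rule and binding that produced it."""

    triple: Tuple[Term, Term, Term]
    rule_name: str
    binding: Tuple[Tuple[str, Term], ...]
    supporting_records: Tuple[URIRef, ...] = ()


@dataclass
class DerivationIndex:
    """Side index: emitted triple → derivation records (possibly several)."""

    records: Dict[Tuple[Term, Term, Term], List[DerivationRecord]] = field(default_factory=dict)

    def add(self, rec: DerivationRecord) -> None:
        bucket = self.records.setdefault(rec.triple, [])
        if rec not in bucket:
            bucket.append(rec)

    def lookup(self, triple: Tuple[Term, Term, Term]) -> List[DerivationRecord]:
        return list(self.records.get(triple, ()))

    def all_triples(self) -> Set[Tuple[Term, Term, Term]]:
        return set(self.records)


# ---------------------------------------------------------------------------
# Matching


def _transitive_objects(graph: Graph, subject: Term, base: URIRef) -> Set[Term]:
    """Reflexive-transitive closure of ``base`` starting at ``subject``."""
    seen: Set[Term] = {subject}
    frontier = [subject]
    while frontier:
        node = frontier.pop()
        for obj in graph.objects(node, base):
            if obj not in seen:
                seen.add(obj)
                frontier.append(obj)
    return seen


def _match_pattern(graph: Graph, pattern: Triple, binding: Dict[str, Term]) -> Iterable[Dict[str, Term]]:
    s, p, o = (binding.get(t.name, t) if isinstance(t, Var) else t for t in pattern)
    if isinstance(p, TransitivePredicate):
        if isinstance(s, Var):
            raise ValueError("transitive pattern requires a bound subject")
        for obj in _transitive_objects(graph, s, p.base):
            if isinstance(o, Var):
                yield {**binding, o.name: obj}
            elif obj == o:
                yield dict(binding)
        return
    query = tuple(None if isinstance(t, Var) else t for t in (s, p, o))
    for ts, tp, to in graph.triples(query):
        new = dict(binding)
        ok = True
        for var, val in zip((s, p, o), (ts, tp, to)):
            if isinstance(var, Var):
                if var.name in new and new[var.name] != val:
                    ok = False
                    break
                new[var.name] = val
        if ok:
            yield new


def match(body: Sequence[Triple], graph: Graph) -> List[Dict[str, Term]]:
    """All binding sets satisfying the body conjunctively, without duplicates.

    Deterministic: results are sorted by their string rendering, so rule
    application order never depends on graph-store iteration order.
    """
    if not body:
        raise ValueError("rule body must be non-empty")
    bindings: List[Dict[str, Term]] = [{}]
    for pattern in body:
        bindings = [nb for b in bindings for nb in _match_pattern(graph, pattern, b)]
        if not bindings:
            return []
    unique: Dict[FrozenSet[Tuple[str, str]], Dict[str, Term]] = {}
    for b in bindings:
        unique.setdefault(frozenset((k, str(v)) for k, v in b.items()), b)
    return sorted(unique.values(), key=lambda b: sorted((k, str(v)) for k, v in b.items()))


def instantiate(
    head: Sequence[Triple],
    binding: Mapping[str, Term],
    mint: Mapping[str, MintDirective] = (),
) -> Tuple[List[Tuple[Term, Term, Term]], Dict[str, Term]]:
    """Substitute a binding into the head, minting fresh URIs as directed.

    Mint directives may reference each other; they are resolved to a fixpoint
    and a cycle raises :class:`UnboundVariable`. Returns the emitted triples
    and the full (body + minted) binding.
    """
    full: Dict[str, Term] = dict(binding)
    pending = dict(mint)
    while pending:
        progressed = False
        for name, directive in list(pending.items()):
            try:
                full[name] = directive.mint(full)
            except UnboundVariable:
                continue
            del pending[name]
            progressed = True
        if not progressed:
            raise UnboundVariable(f"circular or unsatisfiable mint directives: {sorted(pending)}")
    triples: List[Tuple[Term, Term, Term]] = []
    for pattern in head:
        resolved = []
        for t in pattern:
            if isinstance(t, Var):
                if t.name not in full:
                    raise UnboundVariable(f"head variable ?{t.name} has no binding or mint directive")
                resolved.append(full[t.name])
            else:
                resolved.append(t)
        triples.append(tuple(resolved))
    return triples, full


def expand_macro_assertion(x: URIRef, z: URIRef) -> List[Tuple[Term, Term, Term]]:
    """Expand one ``X kiao:denotesSubClassOf Z`` assertion into its two triples."""
    y = mint_bio_class_uri("denoted", [str(x)])
    return [(x, DENOTES, y), (y, RDFS.subClassOf, z)]


def expand_macro(graph: Graph) -> List[Tuple[Term, Term, Term]]:
    """Expand every ``X kiao:denotesSubClassOf Z`` assertion in the graph.

    Each assertion entails exactly two triples — ``X iao:denotes Y`` and
    ``Y rdfs:subClassOf Z`` — where the intermediate concept Y is minted
    deterministically from X, so expanding twice yields the same Y and the
    same pair.
    """
    out: List[Tuple[Term, Term, Term]] = []
    for x, _, z in sorted(graph.triples((None, DENOTES_SUBCLASS_OF, None))):
        out.extend(expand_macro_assertion(x, z))
    return out


@dataclass
class RuleApplication:
    rule_name: str
    new_concept_triples: int = 0
    new_mention_triples: int = 0
    bindings: int = 0

    @property
    def new_triples(self) -> int:
        return self.new_concept_triples + self.new_mention_triples


def apply_rule(
    rule: Rule,
    graph: Graph,
    derivations: Optional[DerivationIndex] = None,
) -> RuleApplication:
    """Apply one rule once: match, instantiate, add novel triples."""
    report = RuleApplication(rule_name=rule.name)
    for binding in match(rule.body, graph):
        report.bindings += 1
        triples, full = instantiate(rule.head, binding, rule.mint)
        for rec_var, concept_var in rule.mentions:
            triples.append((full[rec_var], MENTIONS, full[concept_var]))
        supporting = tuple(full[v] for v in rule.record_vars if v in full)
        for t in triples:
            novel = t not in graph
            if novel:
                graph.add(t)
                if t[1] == MENTIONS:
                    report.new_mention_triples += 1
                else:
                    report.new_concept_triples += 1
            if derivations is not None:
                derivations.add(
                    DerivationRecord(
                        triple=t,
                        rule_name=rule.name,
                        binding=tuple(sorted(binding.items())),
                        supporting_records=supporting,
                    )
                )
    return report


def run_batch_to_fixpoint(
    batch: RuleBatch,
    graph: Graph,
    derivations: Optional[DerivationIndex] = None,
    max_iterations: int = 50,
) -> Dict[str, int]:
    """Run a batch repeatedly until an iteration adds zero new triples.

    Returns per-rule emission counts (novel triples attributed to each rule);
    a zero count for a rule flags a broken mapping. Raises
    :class:`NonTermination` if the bound is exceeded.
    """
    counts: Dict[str, int] = {r.name: 0 for r in batch.rules}
    for _ in range(max_iterations):
        added = 0
        for rule in batch.rules:
            report = apply_rule(rule, graph, derivations)
            counts[rule.name] += report.new_triples
            added += report.new_triples
        if added == 0:
            return counts
    raise NonTermination(f"batch {batch.label!r} did not reach fixpoint in {max_iterations} iterations")


# ---------------------------------------------------------------------------
# Declarative rule files


def _parse_triple(raw: Sequence[str], namespaces: NamespaceTable) -> Triple:
    if len(raw) != 3:
        raise ValueError(f"triple pattern needs 3 terms: {raw!r}")
    return tuple(parse_term(t, namespaces) for t in raw)  # type: ignore[return-value]


def parse_rule(mapping: Mapping, namespaces: NamespaceTable = NAMESPACES) -> Rule:
    mint = {
        name: MintDirective(
            kind=spec["kind"],
            components=tuple(spec.get("components") or [spec.get("property"), spec.get("filler")]),
            uri_prefix=spec.get("uri_prefix", "BIO_"),
        )
        for name, spec in (mapping.get("mint") or {}).items()
    }
    return Rule(
        name=mapping["name"],
        body=tuple(_parse_triple(t, namespaces) for t in mapping["body"]),
        head=tuple(_parse_triple(t, namespaces) for t in mapping["head"]),
        mint=mint,
        record_vars=tuple(mapping.get("record_vars", ())),
        mentions=tuple((m["from"].lstrip("?"), m["to"].lstrip("?")) for m in mapping.get("mentions", ())),
    )


def load_rule_batch(path: Path, namespaces: NamespaceTable = NAMESPACES) -> RuleBatch:
    """Load one batch from a declarative YAML rule file."""
    data = yaml.safe_load(Path(path).read_text())
    rules = tuple(parse_rule(r, namespaces) for r in data["rules"])
    return RuleBatch(label=data.get("batch", Path(path).stem), rules=rules)
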