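"""Provenance tracing and source-data quality checks.

Provenance is available two ways. Concept-level: the aboutness links
(``iao:denotes`` / ``iao:mentions``) crossing from the ICE side identify, for
any BIO concept, the identifier ICEs that denote it and the record ICEs whose
information produced it. Triple-level: a derivation index kept beside the
graph records, for every rule-emitted triple, the rule name and binding that
produced it — a triple derived from two redundant sources carries two
derivation records, and any derivation can be replayed by re-instantiating
its rule on its stored binding.

Quality checks query for assertions that should not exist: a biomedical
entity placed in two taxa the ontology declares disjoint, an identifier set
containing two identifiers from one source namespace, and an external
identifier that multiple records of one source map onto.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

from rdflib import Graph, URIRef
from rdflib.namespace import OWL, RDF

from .identity import ExactMatchEdge, IdentifierSet
from .namespaces import (
    CROSSING_PREDICATES,
    DENOTES,
    IN_TAXON,
    MENTIONS,
    partition_of,
)
from .rule_engine import DerivationIndex, DerivationRecord, Rule, RuleBatch, instantiate
from .urimint import DialectTable


class NotBio(ValueError):
    """The URI handed to a concept trace lives in the ICE partition."""


class UnknownTriple(KeyError):
    """The triple is absent from the graph."""


@dataclass(frozen=True)
class QCFinding:
    kind: str  # disjoint-taxa | set-collision | many-to-one-mapping
    offending: Tuple[URIRef, ...]
    evidence: Tuple[Tuple, ...]


@dataclass
class ConceptTrace:
    concept: URIRef
    denoting_identifiers: List[URIRef] = field(default_factory=list)
    mentioning_records: List[URIRef] = field(default_factory=list)


def trace_concept(bio_uri: URIRef, graph: Graph) -> ConceptTrace:
    """All ICE nodes linked by denotes/mentions to a BIO concept."""
    if partition_of(bio_uri) == "ice":
        raise NotBio(f"{bio_uri} is an information content entity, not a BIO concept")
    return ConceptTrace(
        concept=bio_uri,
        denoting_identifiers=sorted(graph.subjects(DENOTES, bio_uri)),
        mentioning_records=sorted(graph.subjects(MENTIONS, bio_uri)),
    )


def trace_triple(triple: Tuple, graph: Graph, derivations: DerivationIndex) -> List[DerivationRecord]:
    if triple not in graph:
        raise UnknownTriple(f"triple not in graph: {triple}")
    return derivations.lookup(triple)


def replay(record: DerivationRecord, batches: Sequence[RuleBatch]) -> bool:
    """Re-instantiate the named rule on the stored binding; True if the triple
    is re-emitted (soundness check for the derivation index)."""
    rule: Optional[Rule] = None
    for batch in batches:
        for r in batch.rules:
            if r.name == record.rule_name:
                rule = r
    if rule is None:
        return False
    triples, full = instantiate(rule.head, dict(record.binding), rule.mint)
    for rec_var, concept_var in rule.mentions:
        triples.append((full[rec_var], MENTIONS, full[concept_var]))
    return record.triple in triples


def partition_violations(graph: Graph) -> List[Tuple]:
    """Triples crossing ICE→BIO by any predicate other than the aboutness trio."""
    bad = []
    for s, p, o in graph:
        if partition_of(s) == "ice" and partition_of(o) == "bio" and p not in CROSSING_PREDICATES:
            bad.append((s, p, o))
    return bad


def derivation_completeness(rule_emitted: Set[Tuple], derivations: DerivationIndex) -> bool:
    """Every rule-emitted triple has at least one derivation record, and the
    index holds no stray triples."""
    return rule_emitted == derivations.all_triples()


# ---------------------------------------------------------------------------
# Quality checks


def _disjoint_taxa(graph: Graph) -> List[QCFinding]:
    disjoint: Set[Tuple[URIRef, URIRef]] = set()
    for a, _, b in graph.triples((None, OWL.disjointWith, None)):
        disjoint.add((a, b))
        disjoint.add((b, a))
    findings = []
    for entity in sorted(set(graph.subjects(IN_TAXON, None))):
        taxa = sorted(graph.objects(entity, IN_TAXON))
        for i, t1 in enumerate(taxa):
            for t2 in taxa[i + 1 :]:
                if (t1, t2) in disjoint:
                    findings.append(
                        QCFinding(
                            kind="disjoint-taxa",
                            offending=(entity,),
                            evidence=((entity, IN_TAXON, t1), (entity, IN_TAXON, t2)),
                        )
                    )
    return findings


def _set_collisions(id_sets: Sequence[IdentifierSet], dialects: DialectTable) -> List[QCFinding]:
    findings = []
    for idset in id_sets:
        by_space: Dict[str, List[URIRef]] = {}
        for m in idset.members:
            space = dialects.source_of(m) or "?"
            by_space.setdefault(space, []).append(m)
        for space in sorted(by_space):
            members = by_space[space]
            if len(members) >= 2:
                findings.append(
                    QCFinding(
                        kind="set-collision",
                        offending=(idset.uri, *members),
                        evidence=tuple((idset.uri, "member", m) for m in members),
                    )
                )
    return findings


def _many_to_one(edges: Sequence[ExactMatchEdge], graph: Graph) -> List[QCFinding]:
    """External identifiers receiving exact matches from ≥2 records of one source."""
    # target id → source record-class → {(record, other id)}
    seen: Dict[URIRef, Dict[URIRef, Set[Tuple[URIRef, URIRef]]]] = {}
    for edge in edges:
        record_class = next(graph.objects(edge.provenance_record, RDF.type), None)
        for target, other in ((edge.left, edge.right), (edge.right, edge.left)):
            seen.setdefault(target, {}).setdefault(record_class, set()).add((edge.provenance_record, other))
    findings = []
    for target in sorted(seen):
        for record_class, pairs in sorted(seen[target].items()):
            records = {r for r, _ in pairs}
            others = {o for _, o in pairs}
            if len(records) >= 2 and len(others) >= 2:
                findings.append(
                    QCFinding(
                        kind="many-to-one-mapping",
                        offending=(target,),
                        evidence=tuple(sorted((r, "maps", target) for r, _ in pairs)),
                    )
                )
    return findings


def run_qc(
    graph: Graph,
    id_sets: Sequence[IdentifierSet],
    edges: Sequence[ExactMatchEdge],
    dialects: DialectTable,
) -> List[QCFinding]:
    """All quality findings, each citing concrete graph evidence."""
    findings = _disjoint_taxa(graph)
    findings.extend(_set_collisions(id_sets, dialects))
    findings.extend(_many_to_one(edges, graph))
    return findings


def format_qc_report(findings: Sequence[QCFinding]) -> str:
    if not findings:
        return "QC: 0 findings\n"
    lines = [f"QC: {len(findings)} findings"]
    for f in findings:
        lines.append(f"[{f.kind}] offending: {', '.join(str(u) for u in f.offending)}")
        for ev in f.evidence:
            lines.append(f"    evidence: {' '.join(str(t) for t in ev)}")
    return "\n".join(lines) + "\n"
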