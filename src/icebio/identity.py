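"""Identifier identity resolution across sources.

Four stages, each independently inspectable:

1. **Entity typing** — every canonical identifier ICE is asserted to denote a
   subclass of an ontology class for its identifier space (gene ids → a DNA
   sequence class, protein ids → a protein class, ...) via the
   ``kiao:denotesSubClassOf`` macrorelation. This bootstraps type information
   before any biomedical entity exists.
2. **Exact-match extraction** — mapping records propose identifier pairs; a
   pair becomes a ``skos:exactMatch`` edge only when both identifiers' denoted
   types are compatible (identical, or one subsumes the other in the loaded
   ontology). Cross-type candidates (gene↔protein, gene↔disease in a dbXref
   field) are filtered and counted, never linked.
3. **Union-find closure** — exact-match edges are closed into disjoint
   identifier sets (connected components); identifiers with no edges form
   singleton sets so every identifier yields a biomedical entity downstream.
4. **Materialization** — each set gets a permutation-invariant hashed URI and
   one ``kro:hasMember`` triple per member; each set then yields exactly one
   BIO concept class that every member ``iao:denotes``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from rdflib import Graph, URIRef
from rdflib.namespace import RDF, RDFS

from .namespaces import (
    DENOTES,
    DENOTES_SUBCLASS_OF,
    EXACT_MATCH,
    HAS_IDENTIFIER,
    HAS_MEMBER,
    HAS_PART,
    HAS_TEMPLATE,
    IDENTIFIER_ICE,
    IDENTIFIER_SPACE,
)
from .source_io import BuildLog
from .urimint import mint_bio_class_uri, mint_set_uri

Triple = Tuple


class MixedTypeSet(ValueError):
    """Members of one identifier set carry incompatible denoted types."""


@dataclass(frozen=True)
class ExactMatchEdge:
    left: URIRef
    right: URIRef
    provenance_record: URIRef


@dataclass(frozen=True)
class IdentifierSet:
    uri: URIRef
    members: Tuple[URIRef, ...]  # sorted

    @classmethod
    def of(cls, members: Iterable[URIRef]) -> "IdentifierSet":
        sorted_members = tuple(sorted(set(members)))
        return cls(uri=mint_set_uri(sorted_members), members=sorted_members)


def apply_entity_typing(
    graph: Graph,
    typemap: Mapping[str, URIRef],
    log: Optional[BuildLog] = None,
) -> int:
    """Assert ``id kiao:denotesSubClassOf class`` for every typed identifier.

    Identifier spaces absent from ``typemap`` are left ICE-only and logged.
    Returns the number of guard triples added.
    """
    added = 0
    untyped: Set[str] = set()
    for ident in graph.subjects(RDF.type, IDENTIFIER_ICE):
        space = str(next(graph.objects(ident, IDENTIFIER_SPACE), ""))
        if space in typemap:
            t = (ident, DENOTES_SUBCLASS_OF, typemap[space])
            if t not in graph:
                graph.add(t)
                added += 1
        else:
            untyped.add(space)
    if log is not None and untyped:
        log.info(f"entity-typing: identifier spaces left untyped: {sorted(untyped)}")
    return added


def guard_class(graph: Graph, ident: URIRef) -> Optional[URIRef]:
    return next(graph.objects(ident, DENOTES_SUBCLASS_OF), None)


def is_subclass_of(graph: Graph, a: URIRef, b: URIRef) -> bool:
    """Reflexive-transitive rdfs:subClassOf check over the loaded hierarchy."""
    seen = {a}
    frontier = [a]
    while frontier:
        node = frontier.pop()
        if node == b:
            return True
        for parent in graph.objects(node, RDFS.subClassOf):
            if parent not in seen:
                seen.add(parent)
                frontier.append(parent)
    return False


def compatible_types(graph: Graph, left: Optional[URIRef], right: Optional[URIRef]) -> bool:
    if left is None or right is None:
        return False
    return left == right or is_subclass_of(graph, left, right) or is_subclass_of(graph, right, left)


@dataclass(frozen=True)
class MappingFieldPair:
    """Which field pair of which schema proposes identity candidates."""

    schema_label: str
    left_field: str
    right_field: str


def _record_field_identifiers(graph: Graph, record: URIRef, field_uri: URIRef) -> List[URIRef]:
    ids: List[URIRef] = []
    for fv in graph.objects(record, HAS_PART):
        if (fv, HAS_TEMPLATE, field_uri) in graph:
            ids.extend(graph.objects(fv, HAS_IDENTIFIER))
    return sorted(ids)


@dataclass
class ExtractionReport:
    edges: List[ExactMatchEdge] = field(default_factory=list)
    filtered: int = 0
    filtered_pairs: List[Tuple[URIRef, URIRef]] = field(default_factory=list)


def extract_exact_matches(
    graph: Graph,
    pairs: Sequence[MappingFieldPair],
    log: Optional[BuildLog] = None,
) -> ExtractionReport:
    """Emit type-guarded ``skos:exactMatch`` edges from mapping records.

    Filtering is the success path: candidates whose guard types are
    incompatible are counted, logged and skipped. Accepted edges are written
    to the graph (subject/object in sorted order for determinism) and retain
    the proposing record as provenance.
    """
    from .namespaces import KIAO

    report = ExtractionReport()
    for spec in pairs:
        record_class = URIRef(f"{KIAO}Record_{spec.schema_label}")
        left_uri = URIRef(f"{KIAO}Field_{spec.schema_label}_{spec.left_field}")
        right_uri = URIRef(f"{KIAO}Field_{spec.schema_label}_{spec.right_field}")
        for record in sorted(graph.subjects(RDF.type, record_class)):
            lefts = _record_field_identifiers(graph, record, left_uri)
            rights = _record_field_identifiers(graph, record, right_uri)
            for lid in lefts:
                for rid in rights:
                    if lid == rid:
                        continue
                    if compatible_types(graph, guard_class(graph, lid), guard_class(graph, rid)):
                        a, b = sorted((lid, rid))
                        graph.add((a, EXACT_MATCH, b))
                        report.edges.append(ExactMatchEdge(a, b, record))
                    else:
                        report.filtered += 1
                        report.filtered_pairs.append((lid, rid))
    if log is not None:
        log.info(
            f"exact-match extraction: {len(report.edges)} edges emitted, "
            f"{report.filtered} cross-type candidates filtered"
        )
    return report


class UnionFind:
    """Disjoint-set forest with union by size and path compression."""

    def __init__(self, universe: Iterable[URIRef] = ()) -> None:
        self.parent: Dict[URIRef, URIRef] = {}
        self.size: Dict[URIRef, int] = {}
        for item in universe:
            self.add(item)

    def add(self, item: URIRef) -> None:
        if item not in self.parent:
            self.parent[item] = item
            self.size[item] = 1

    def find(self, item: URIRef) -> URIRef:
        root = item
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[item] != root:
            self.parent[item], item = root, self.parent[item]
        return root

    def union(self, a: URIRef, b: URIRef) -> None:
        self.add(a)
        self.add(b)
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return
        if self.size[ra] < self.size[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        self.size[ra] += self.size[rb]

    def components(self) -> List[Tuple[URIRef, ...]]:
        groups: Dict[URIRef, List[URIRef]] = {}
        for item in self.parent:
            groups.setdefault(self.find(item), []).append(item)
        return sorted(tuple(sorted(g)) for g in groups.values())


def union_find_closure(
    edges: Iterable[ExactMatchEdge],
    universe: Iterable[URIRef],
) -> List[IdentifierSet]:
    """Partition the typed-identifier universe by exact-match connectivity.

    The result equals the connected components of the edge graph; edge-less
    identifiers form singleton sets. Output is deterministic: members sorted
    within each set, sets sorted by URI.
    """
    uf = UnionFind(universe)
    for edge in edges:
        uf.union(edge.left, edge.right)
    sets = [IdentifierSet.of(component) for component in uf.components()]
    return sorted(sets, key=lambda s: str(s.uri))


def materialize_id_set(idset: IdentifierSet) -> List[Triple]:
    """Exactly one ``kro:hasMember`` triple per member, and nothing else.

    The set's nature is carried by its URI namespace (``kiao:ID-Set-…``); no
    explicit type triple is emitted, matching the four-triple convention for a
    four-member set.
    """
    return [(idset.uri, HAS_MEMBER, m) for m in idset.members]


def shared_guard_class(graph: Graph, idset: IdentifierSet) -> URIRef:
    """Most specific denoted type shared by all members; MixedTypeSet otherwise."""
    guards = []
    for m in idset.members:
        g = guard_class(graph, m)
        if g is not None:
            guards.append(g)
    if not guards:
        raise MixedTypeSet(f"set {idset.uri} has no typed members")
    most_specific = guards[0]
    for g in guards[1:]:
        if is_subclass_of(graph, g, most_specific):
            most_specific = g
        elif not is_subclass_of(graph, most_specific, g):
            raise MixedTypeSet(f"set {idset.uri} mixes incompatible types {most_specific} / {g}")
    return most_specific


def create_bio_entity(graph: Graph, idset: IdentifierSet) -> Tuple[URIRef, List[Triple]]:
    """One BIO concept class per identifier set.

    The class URI is a hash of the set URI; it is asserted
    ``rdfs:subClassOf`` the members' shared ontology type, and every member
    identifier ICE ``iao:denotes`` it — the only triples crossing the ICE/BIO
    divide at this stage.
    """
    parent = shared_guard_class(graph, idset)
    bio = mint_bio_class_uri("set", [str(idset.uri)])
    triples: List[Triple] = [(bio, RDFS.subClassOf, parent)]
    for m in idset.members:
        triples.append((m, DENOTES, bio))
    return bio, triples
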