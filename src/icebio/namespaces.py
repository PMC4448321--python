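"""Namespace table and fixed vocabulary terms.

The knowledge base is partitioned into three URI regions:

* ``kiao:`` — information content entities (ICE): databases, schemas, records,
  fields, field values, identifiers, identifier sets.
* ``kbio:`` — generated biomedical concept classes (BIO): genes, proteins,
  process subclasses, interaction subclasses, OWL restrictions, aggregates.
* ``obo:`` — imported ontology vocabulary (sequence types, processes, taxa,
  relations), loaded verbatim and never asserted on directly.

The table is immutable during a build; prefixes are unique and bases end in
"/" or "#".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping

from rdflib import Namespace, URIRef
from rdflib.namespace import OWL, RDF, RDFS, SKOS

KIAO = Namespace("http://icebio.example.org/kiao/")
KBIO = Namespace("http://icebio.example.org/kbio/")
KRO = Namespace("http://icebio.example.org/kro/")
OBO = Namespace("http://purl.obolibrary.org/obo/")
IAO = Namespace("http://purl.obolibrary.org/obo/IAO_")

_DEFAULT_TABLE: Mapping[str, str] = MappingProxyType(
    {
        "kiao": str(KIAO),
        "kbio": str(KBIO),
        "kro": str(KRO),
        "iao": str(IAO),
        "obo": str(OBO),
        "skos": str(SKOS),
        "rdf": str(RDF),
        "rdfs": str(RDFS),
        "owl": str(OWL),
    }
)


class NamespaceError(ValueError):
    """Raised for malformed or conflicting namespace declarations."""


@dataclass(frozen=True)
class NamespaceTable:
    """Immutable prefix → base-URI table used to expand CURIEs.

    Parameters
    ----------
    extra:
        Additional prefix/base pairs layered over the built-in table. A prefix
        already present may not be re-bound to a different base.
    """

    extra: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        table = dict(_DEFAULT_TABLE)
        for prefix, base in self.extra.items():
            if prefix in table and table[prefix] != base:
                raise NamespaceError(f"prefix {prefix!r} already bound")
            if not (base.startswith("http://") or base.startswith("https://")):
                raise NamespaceError(f"base for {prefix!r} is not absolute: {base!r}")
            if not base.endswith(("/", "#")):
                raise NamespaceError(f"base for {prefix!r} must end in '/' or '#'")
            table[prefix] = base
        object.__setattr__(self, "_table", MappingProxyType(table))

    @property
    def table(self) -> Mapping[str, str]:
        return self._table  # type: ignore[attr-defined]

    def expand(self, curie_or_uri: str) -> URIRef:
        """Expand a ``prefix:local`` CURIE; absolute URIs pass through."""
        if curie_or_uri.startswith(("http://", "https://")):
            return URIRef(curie_or_uri)
        prefix, sep, local = curie_or_uri.partition(":")
        if not sep or prefix not in self.table:
            raise NamespaceError(f"cannot expand {curie_or_uri!r}")
        return URIRef(self.table[prefix] + local)

    def bind_all(self, graph) -> None:
        for prefix, base in self.table.items():
            graph.bind(prefix, Namespace(base))


NAMESPACES = NamespaceTable()

# Aboutness relations (Information Artifact Ontology) — the only predicates
# permitted to cross from the ICE partition into the BIO partition.
DENOTES = OBO.IAO_0000219
MENTIONS = OBO.IAO_0000142
IS_ABOUT = OBO.IAO_0000136
CROSSING_PREDICATES = frozenset({DENOTES, MENTIONS, IS_ABOUT})

# Record / template structure.
HAS_PART = OBO.BFO_0000051
HAS_TEMPLATE = KIAO.hasTemplate
HAS_LITERAL_VALUE = KIAO.hasLiteralValue
HAS_IDENTIFIER = KIAO.hasIdentifier
CANONICAL_FORM = KIAO.hasCanonicalForm
IDENTIFIER_SPACE = KIAO.identifierSpace
IDENTIFIER_ICE = KIAO.IdentifierICE

# Identifier identity machinery.
DENOTES_SUBCLASS_OF = KIAO.denotesSubClassOf
EXACT_MATCH = SKOS.exactMatch
HAS_MEMBER = KRO.hasMember

# BIO-side relations.
HAS_PARTICIPANT = OBO.RO_0000057
IN_TAXON = OBO.RO_0002162
LOCATED_IN = OBO.RO_0001025
INDIRECTLY_TEMPLATES = KRO.indirectlyTemplates  # gene → protein; see docs/methods.md


def partition_of(term) -> str:
    """Classify a URI as ``ice``, ``bio``, ``onto`` or ``other``."""
    s = str(term)
    if s.startswith(str(KIAO)):
        return "ice"
    if s.startswith(str(KBIO)):
        return "bio"
    if s.startswith(str(OBO)):
        return "onto"
    return "other"
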