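"""Explicit representation of source records as information content entities.

Each database, schema, record, field, and field value is modeled as an ICE.
A record node is linked to its schema via ``kiao:hasTemplate`` and to each of
its field-value nodes via ``obo:has_part`` (record-centric direction). A
field-value node is defined by exactly three triples:

1. ``rdf:type`` to the per-schema field-value class,
2. ``kiao:hasTemplate`` to its field ICE,
3. a value triple — ``kiao:hasLiteralValue`` with the source string for plain
   fields, or ``kiao:hasIdentifier`` pointing to the globally shared canonical
   identifier ICE for identifier-designated fields.

Field-value nodes are hash-minted from (schema, field, value) and shared by
every record that carries the same value in the same field, so their three
defining triples are emitted once per distinct value, not once per record.
Canonical identifier ICEs are likewise defined by exactly three triples (type,
canonical lexical form, identifier space) emitted on first sight.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from rdflib import Graph, Literal, URIRef
from rdflib.namespace import RDF

from .namespaces import (
    CANONICAL_FORM,
    HAS_IDENTIFIER,
    HAS_LITERAL_VALUE,
    HAS_PART,
    HAS_TEMPLATE,
    IDENTIFIER_ICE,
    IDENTIFIER_SPACE,
    KIAO,
)
from .urimint import DialectTable, FieldContext, mint_field_value_uri, mint_record_uri

Triple = Tuple[URIRef, URIRef, object]


class SchemaMismatch(KeyError):
    """A parsed row carries a field name absent from its schema."""


@dataclass(frozen=True)
class FieldTemplate:
    name: str
    schema_label: str
    identifier_source: Optional[str] = None  # dialect whose bare forms this field may hold
    is_identifier: bool = False  # identifier-bearing even without a bare-form source
    primary_key: bool = False
    mandatory: bool = True

    @property
    def holds_identifiers(self) -> bool:
        return self.is_identifier or self.identifier_source is not None

    @property
    def uri(self) -> URIRef:
        return URIRef(f"{KIAO}Field_{self.schema_label}_{self.name}")

    @property
    def context(self) -> FieldContext:
        return FieldContext(self.schema_label, self.name, self.identifier_source)


@dataclass(frozen=True)
class SchemaTemplate:
    """Declarative description of one delimited source file layout."""

    database_label: str
    label: str
    fields: Tuple[FieldTemplate, ...]
    delimiter: str = "\t"
    has_header: bool = True

    def __post_init__(self) -> None:
        names = [f.name for f in self.fields]
        if len(names) != len(set(names)):
            raise ValueError(f"duplicate field names in schema {self.label!r}")

    @property
    def uri(self) -> URIRef:
        return URIRef(f"{KIAO}Schema_{self.label}")

    @property
    def record_class(self) -> URIRef:
        return URIRef(f"{KIAO}Record_{self.label}")

    @property
    def field_value_class(self) -> URIRef:
        return URIRef(f"{KIAO}FieldValue_{self.label}")

    def field(self, name: str) -> FieldTemplate:
        for f in self.fields:
            if f.name == name:
                return f
        raise SchemaMismatch(f"field {name!r} not in schema {self.label!r}")

    @classmethod
    def from_config(cls, mapping: Mapping) -> "SchemaTemplate":
        label = mapping["label"]
        fields = tuple(
            FieldTemplate(
                name=f["name"],
                schema_label=label,
                identifier_source=f.get("identifier_source"),
                is_identifier=bool(f.get("is_identifier", False)),
                primary_key=bool(f.get("primary_key", False)),
                mandatory=bool(f.get("mandatory", True)),
            )
            for f in mapping["fields"]
        )
        return cls(
            database_label=mapping.get("database", label),
            label=label,
            fields=fields,
            delimiter=mapping.get("delimiter", "\t"),
            has_header=bool(mapping.get("has_header", True)),
        )

    def schema_triples(self) -> List[Triple]:
        """Schema and field ICE declarations (schema has_part each field)."""
        triples: List[Triple] = [(self.uri, RDF.type, KIAO.Schema)]
        for f in self.fields:
            triples.append((self.uri, HAS_PART, f.uri))
            triples.append((f.uri, RDF.type, KIAO.Field))
        return triples


@dataclass
class Rdfizer:
    """Stateful record → triples converter with graph-wide field-value sharing."""

    dialects: DialectTable
    _seen_field_values: Set[URIRef] = field(default_factory=set)
    _seen_identifiers: Set[URIRef] = field(default_factory=set)
    _raw_fv_triples: int = 0
    _dedup_fv_triples: int = 0

    def rdfize_record(self, row: Mapping[str, str], schema: SchemaTemplate) -> Tuple[URIRef, List[Triple]]:
        """Emit the record node, its part links, and any new defining triples.

        ``row`` maps field names to raw (uncanonicalized) values; keys must be
        a subset of the schema's field names. Empty-string values are skipped
        (no field-value node is minted for them). Identifier-designated values
        are canonicalized here.
        """
        for key in row:
            if key not in {f.name for f in schema.fields}:
                raise SchemaMismatch(f"row key {key!r} not in schema {schema.label!r}")

        record_uri = self._record_uri(row, schema)
        triples: List[Triple] = [
            (record_uri, RDF.type, schema.record_class),
            (record_uri, HAS_TEMPLATE, schema.uri),
        ]
        for f in schema.fields:
            raw = (row.get(f.name) or "").strip()
            if not raw:
                continue
            # Multi-valued fields (dbXref style) are pipe-separated.
            values = raw.split("|") if "|" in raw else [raw]
            for value in values:
                value = value.strip()
                if not value:
                    continue
                fv = self._field_value(value, f, schema, triples)
                triples.append((record_uri, HAS_PART, fv))
        return record_uri, triples

    def _record_uri(self, row: Mapping[str, str], schema: SchemaTemplate) -> URIRef:
        pk_fields = [f for f in schema.fields if f.primary_key]
        if pk_fields:
            key = "|".join((row.get(f.name) or "").strip() for f in pk_fields)
        else:
            key = "|".join(f"{f.name}={(row.get(f.name) or '').strip()}" for f in schema.fields)
        return mint_record_uri(str(schema.uri), key)

    def _field_value(
        self,
        value: str,
        f: FieldTemplate,
        schema: SchemaTemplate,
        triples: List[Triple],
    ) -> URIRef:
        if f.holds_identifiers:
            ident = self.dialects.canonicalize(value, f.context)
            # Mint the wrapper from the canonical form so lexical dialects of
            # one identifier share a single field-value node per field.
            fv = mint_field_value_uri(schema.label, f.name, str(ident))
            value_triple: Triple = (fv, HAS_IDENTIFIER, ident)
            if ident not in self._seen_identifiers:
                self._seen_identifiers.add(ident)
                space = self.dialects.source_of(ident) or ""
                local = str(ident).rsplit("/", 1)[-1]
                triples.extend(
                    [
                        (ident, RDF.type, IDENTIFIER_ICE),
                        (ident, CANONICAL_FORM, Literal(local[: -len("_ICE")] if local.endswith("_ICE") else local)),
                        (ident, IDENTIFIER_SPACE, Literal(space)),
                    ]
                )
        else:
            fv = mint_field_value_uri(schema.label, f.name, value)
            value_triple = (fv, HAS_LITERAL_VALUE, Literal(value))

        self._raw_fv_triples += 3
        if fv not in self._seen_field_values:
            self._seen_field_values.add(fv)
            self._dedup_fv_triples += 3
            triples.extend(
                [
                    (fv, RDF.type, schema.field_value_class),
                    (fv, HAS_TEMPLATE, f.uri),
                    value_triple,
                ]
            )
        return fv

    def triple_reduction_stats(self) -> Dict[str, float]:
        """Field-value triple savings from node sharing across the batch.

        ``reduction`` is ``1 - deduplicated/raw`` over the three defining
        triples of each field-value occurrence; 0.0 when every value is
        distinct.
        """
        raw = self._raw_fv_triples
        dedup = self._dedup_fv_triples
        reduction = 0.0 if raw == 0 else 1.0 - dedup / raw
        return {
            "raw_field_value_triples": raw,
            "deduplicated_field_value_triples": dedup,
            "percent_reduction": round(100.0 * reduction, 2),
        }


def rdfize_rows(
    rows: Iterable[Mapping[str, str]],
    schema: SchemaTemplate,
    rdfizer: Rdfizer,
    graph: Optional[Graph] = None,
) -> Tuple[Graph, List[URIRef]]:
    """RDFize a row stream into ``graph`` (new graph if omitted)."""
    g = graph if graph is not None else Graph()
    for t in schema.schema_triples():
        g.add(t)
    record_uris: List[URIRef] = []
    for row in rows:
        record_uri, triples = rdfizer.rdfize_record(row, schema)
        record_uris.append(record_uri)
        for t in triples:
            g.add(t)
    return g, record_uris
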