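"""Readers for the formats the pipeline touches, plus build logging.

Three readers cover the desk-scale surface: schema-driven delimited files
(TSV/CSV), GAF 2.x gene-association files, and RDF ontologies (Turtle or
RDF/XML). Malformed rows are quarantined with a warning — never silently
dropped — and every parse produces a :class:`ParseReport` whose arithmetic
always balances (rows read = emitted + quarantined).
"""

from __future__ import annotations

import csv
import datetime as _dt
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterator, List, Optional, Tuple

import networkx as nx
from rdflib import Graph
from rdflib.namespace import RDFS

from .ice_model import SchemaTemplate

logger = logging.getLogger("icebio.build")


class MissingColumns(ValueError):
    """Mandatory schema columns are absent — the source file format changed."""


class OntologyParseError(ValueError):
    """Ontology files are the vocabulary backbone; a parse failure aborts."""


@dataclass(frozen=True)
class SourceFileDescriptor:
    path: Path
    format: str  # delimited | gaf | rdf-ontology
    schema_label: Optional[str] = None
    origin: str = "local-fixture"
    download_date: Optional[str] = None

    def log_provenance(self, log: "BuildLog") -> None:
        date = self.download_date or _dt.date.today().isoformat()
        log.info(f"source file={self.path.name} origin={self.origin} date={date} format={self.format}")


@dataclass
class ParseReport:
    file: str
    rows_read: int = 0
    rows_emitted: int = 0
    rows_quarantined: int = 0
    warnings: List[str] = field(default_factory=list)

    def warn(self, message: str) -> None:
        self.warnings.append(message)
        logger.warning("%s: %s", self.file, message)

    def balanced(self) -> bool:
        return self.rows_read == self.rows_emitted + self.rows_quarantined


@dataclass
class BuildLog:
    """Line-oriented build log, mirrored to the Python logger."""

    path: Optional[Path] = None
    lines: List[str] = field(default_factory=list)

    def info(self, message: str) -> None:
        self.lines.append(message)
        logger.info(message)
        if self.path is not None:
            with open(self.path, "a") as fh:
                fh.write(message + "\n")


def read_delimited(
    descriptor: SourceFileDescriptor, schema: SchemaTemplate
) -> Tuple[List[Dict[str, str]], ParseReport]:
    """Parse a delimited file against its schema.

    Unknown extra columns are carried with a warning (format-drift detection);
    missing mandatory columns raise :class:`MissingColumns`; short rows are
    quarantined.
    """
    report = ParseReport(file=str(descriptor.path))
    rows: List[Dict[str, str]] = []
    schema_names = [f.name for f in schema.fields]
    with open(descriptor.path, newline="") as fh:
        reader = csv.reader(fh, delimiter=schema.delimiter)
        header = schema_names
        if schema.has_header:
            try:
                header = next(reader)
            except StopIteration as exc:
                raise MissingColumns(f"{descriptor.path}: empty file") from exc
            mandatory = [f.name for f in schema.fields if f.mandatory]
            missing = [name for name in mandatory if name not in header]
            if missing:
                raise MissingColumns(f"{descriptor.path}: missing mandatory columns {missing}")
            extra = [name for name in header if name not in schema_names]
            for name in extra:
                report.warn(f"unknown column {name!r} ignored")
        for raw in reader:
            report.rows_read += 1
            if len(raw) < len([h for h in header if h in schema_names]):
                report.rows_quarantined += 1
                report.warn(f"row {report.rows_read}: expected {len(header)} columns, got {len(raw)}")
                continue
            row = {name: value for name, value in zip(header, raw) if name in schema_names}
            rows.append(row)
            report.rows_emitted += 1
    return rows, report


#: GAF 2.x column names, pinned to the 17-column layout.
GAF_COLUMNS = (
    "DB",
    "DB_Object_ID",
    "DB_Object_Symbol",
    "Qualifier",
    "GO_ID",
    "DB_Reference",
    "Evidence_Code",
    "With_From",
    "Aspect",
    "DB_Object_Name",
    "DB_Object_Synonym",
    "DB_Object_Type",
    "Taxon",
    "Date",
    "Assigned_By",
    "Annotation_Extension",
    "Gene_Product_Form_ID",
)


def gaf_schema(database_label: str = "goa") -> SchemaTemplate:
    """Schema consuming the identifier-bearing GAF columns.

    Columns 1–2 (DB, DB Object ID), 5 (GO ID), 7 (evidence) and 13 (taxon) are
    modeled as field values; the remaining columns are carried opaquely on the
    parsed rows but not RDFized.
    """
    from .ice_model import FieldTemplate

    label = database_label
    fields = (
        FieldTemplate("DB", label),
        FieldTemplate("DB_Object_ID", label, identifier_source="UP", primary_key=True),
        FieldTemplate("GO_ID", label, identifier_source="GO", primary_key=True),
        FieldTemplate("Evidence_Code", label, primary_key=True),
        FieldTemplate("Taxon", label, identifier_source="NCBITaxon"),
    )
    return SchemaTemplate(database_label=label, label=label, fields=fields, has_header=False)


def read_gaf(descriptor: SourceFileDescriptor) -> Tuple[List[Dict[str, str]], ParseReport]:
    """Parse a GAF 2.x file: '!'-prefixed comments skipped, 17 columns enforced."""
    report = ParseReport(file=str(descriptor.path))
    rows: List[Dict[str, str]] = []
    with open(descriptor.path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("!"):
                continue
            report.rows_read += 1
            parts = line.split("\t")
            if len(parts) != len(GAF_COLUMNS):
                report.rows_quarantined += 1
                report.warn(f"row {report.rows_read}: {len(parts)} columns, expected {len(GAF_COLUMNS)}")
                continue
            rows.append(dict(zip(GAF_COLUMNS, parts)))
            report.rows_emitted += 1
    return rows, report


def load_ontology(descriptor: SourceFileDescriptor, log: Optional[BuildLog] = None) -> Graph:
    """Load an ontology verbatim into a fresh graph.

    Validation is not this layer's job: a subclass cycle only logs a warning.
    A parse failure aborts because the ontology supplies the vocabulary every
    rule references.
    """
    graph = Graph()
    fmt = "xml" if descriptor.path.suffix in {".owl", ".rdf", ".xml"} else "turtle"
    try:
        graph.parse(descriptor.path, format=fmt)
    except Exception as exc:  # noqa: BLE001 - rdflib raises heterogeneous errors
        raise OntologyParseError(f"cannot parse ontology {descriptor.path}: {exc}") from exc
    if len(graph) == 0:
        raise OntologyParseError(f"ontology {descriptor.path} contains no triples")
    dg = nx.DiGraph((s, o) for s, _, o in graph.triples((None, RDFS.subClassOf, None)))
    if dg.number_of_edges() and not nx.is_directed_acyclic_graph(dg):
        message = f"ontology {descriptor.path.name} has a subclass cycle"
        if log is not None:
            log.info("WARNING " + message)
        logger.warning(message)
    return graph


def gaf_rows_iter(rows: List[Dict[str, str]]) -> Iterator[Dict[str, str]]:
    """Project GAF rows onto the RDFized GAF schema fields."""
    keep = {"DB", "DB_Object_ID", "GO_ID", "Evidence_Code", "Taxon"}
    for row in rows:
        yield {k: v for k, v in row.items() if k in keep}
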