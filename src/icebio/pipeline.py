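"""Build orchestration: the staged construction of the knowledge base.

Stage order is fixed: load ontologies → RDFize source records → mint ICE
identifiers for ontology concepts → entity typing → ICE-to-ICE exact matches
→ identifier sets → BIO entities → BIO rule batches. Each stage writes a
gzip-compressed, sorted N-Triples checkpoint into the working directory, so
any stage's output can be used (or inspected) on its own and a later stage
can be re-run without repeating earlier ones. The graph itself lives in
memory; there is no external triplestore.

Two complete builds from identical inputs produce byte-identical checkpoint
files — every minted URI is a pure hash of its defining values and all
serialization is sorted.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import yaml
from rdflib import Graph, Literal, URIRef
from rdflib.namespace import RDF

from . import bio_builder
from .ice_model import Rdfizer, SchemaTemplate, rdfize_rows
from .identity import (
    ExactMatchEdge,
    IdentifierSet,
    MappingFieldPair,
    apply_entity_typing,
    create_bio_entity,
    extract_exact_matches,
    materialize_id_set,
    union_find_closure,
)
from .namespaces import (
    CANONICAL_FORM,
    DENOTES,
    DENOTES_SUBCLASS_OF,
    HAS_MEMBER,
    IDENTIFIER_ICE,
    IDENTIFIER_SPACE,
    KIAO,
    NAMESPACES,
)
from .provenance_qc import QCFinding, run_qc
from .rule_engine import DerivationIndex, DerivationRecord, load_rule_batch
from .source_io import (
    BuildLog,
    ParseReport,
    SourceFileDescriptor,
    gaf_rows_iter,
    gaf_schema,
    load_ontology,
    read_delimited,
    read_gaf,
)
from .urimint import DialectTable, UnknownDialect, sha1_b64url

STAGE_FILES = {
    "rdfize": "10_ice.nt.gz",
    "match-ids": "20_matches.nt.gz",
    "merge-ids": "30_id_sets.nt.gz",
    "build-bio": "40_bio.nt.gz",
}
STAGE_ORDER = ("rdfize", "match-ids", "merge-ids", "build-bio")


class StageOrderViolation(RuntimeError):
    """A stage was invoked before the stage(s) it depends on produced output."""


@dataclass
class BuildConfig:
    workdir: Path
    ontologies: List[Path]
    sources: List[Dict]
    schemas: Dict[str, SchemaTemplate]
    entity_types: Dict[str, URIRef]
    mapping_pairs: List[MappingFieldPair]
    rule_batches: List[str]
    ontology_id_spaces: List[str] = field(default_factory=lambda: ["GO", "NCBITaxon", "MI"])
    seed: int = 1
    derivations_on: bool = True

    @classmethod
    def from_yaml(cls, path: Path, workdir: Optional[Path] = None) -> "BuildConfig":
        path = Path(path)
        base = path.parent
        data = yaml.safe_load(path.read_text())
        schemas = {name: SchemaTemplate.from_config(cfg) for name, cfg in data.get("schemas", {}).items()}
        return cls(
            workdir=Path(workdir) if workdir else base,
            ontologies=[base / p for p in data.get("ontologies", [])],
            sources=[{**s, "path": base / s["path"]} for s in data.get("sources", [])],
            schemas=schemas,
            entity_types={k: NAMESPACES.expand(v) for k, v in data.get("entity_types", {}).items()},
            mapping_pairs=[
                MappingFieldPair(p["schema"], p["left"], p["right"]) for p in data.get("mapping_pairs", [])
            ],
            rule_batches=list(data.get("rule_batches", [])),
            ontology_id_spaces=list(data.get("ontology_id_spaces", ["GO", "NCBITaxon", "MI"])),
            seed=int(data.get("seed", 1)),
        )


@dataclass
class BuildResult:
    graph: Graph
    derivations: DerivationIndex
    id_sets: List[IdentifierSet]
    edges: List[ExactMatchEdge]
    parse_reports: List[ParseReport]
    reduction_stats: Dict[str, float]
    stage_counts: Dict[str, int]
    rule_counts: Dict[str, int]
    rule_emitted: Set[Tuple]
    bio_entities: Dict[URIRef, URIRef]  # set uri → bio class
    log: BuildLog


# ---------------------------------------------------------------------------
# Serialization helpers


def triple_line(t: Tuple) -> str:
    s, p, o = t
    return f"{s.n3()} {p.n3()} {o.n3()} ."


def write_nt_gz(triples, path: Path) -> int:
    lines = sorted(triple_line(t) for t in triples)
    with gzip.open(path, "wt") as fh:
        fh.write("\n".join(lines) + ("\n" if lines else ""))
    return len(lines)


def read_nt_gz(path: Path, graph: Optional[Graph] = None) -> Graph:
    g = graph if graph is not None else Graph()
    with gzip.open(path, "rt") as fh:
        data = fh.read()
    if data.strip():
        g.parse(data=data, format="nt")
    return g


def triple_hash(t: Tuple) -> str:
    return sha1_b64url(triple_line(t).encode("utf-8"))


def write_derivations(derivations: DerivationIndex, path: Path) -> None:
    """Line-oriented sidecar keyed by triple hash."""
    lines = []
    for triple, records in derivations.records.items():
        for rec in records:
            lines.append(
                "\t".join(
                    [
                        triple_hash(triple),
                        triple_line(triple),
                        rec.rule_name,
                        json.dumps([[k, str(v)] for k, v in rec.binding]),
                        json.dumps([str(r) for r in rec.supporting_records]),
                    ]
                )
            )
    path.write_text("\n".join(sorted(lines)) + ("\n" if lines else ""))


def write_edges(edges: Sequence[ExactMatchEdge], path: Path) -> None:
    lines = sorted(f"{e.left}\t{e.right}\t{e.provenance_record}" for e in edges)
    path.write_text("\n".join(lines) + ("\n" if lines else ""))


def read_edges(path: Path) -> List[ExactMatchEdge]:
    edges = []
    for line in path.read_text().splitlines():
        if line.strip():
            left, right, record = line.split("\t")
            edges.append(ExactMatchEdge(URIRef(left), URIRef(right), URIRef(record)))
    return edges


# ---------------------------------------------------------------------------
# Stages


def _rdfize_stage(config: BuildConfig, log: BuildLog) -> Tuple[Graph, Rdfizer, List[ParseReport]]:
    graph = Graph()
    NAMESPACES.bind_all(graph)
    for onto_path in config.ontologies:
        desc = SourceFileDescriptor(path=Path(onto_path), format="rdf-ontology")
        desc.log_provenance(log)
        onto = load_ontology(desc, log)
        for t in onto:
            graph.add(t)
        log.info(f"loaded ontology {Path(onto_path).name}: {len(onto)} triples")

    dialects = DialectTable.builtin()
    rdfizer = Rdfizer(dialects=dialects)
    reports: List[ParseReport] = []
    for source in config.sources:
        path = Path(source["path"])
        desc = SourceFileDescriptor(path=path, format=source["format"], schema_label=source.get("schema"))
        desc.log_provenance(log)
        if source["format"] == "gaf":
            raw_rows, report = read_gaf(desc)
            rows = list(gaf_rows_iter(raw_rows))
            schema = gaf_schema()
        else:
            schema = config.schemas[source["schema"]]
            rows, report = read_delimited(desc, schema)
        kept = []
        for row in rows:
            try:
                for f in schema.fields:
                    raw = (row.get(f.name) or "").strip()
                    if raw and f.holds_identifiers:
                        for value in raw.split("|"):
                            if value.strip():
                                dialects.canonicalize(value.strip(), f.context)
            except UnknownDialect as exc:
                report.rows_emitted -= 1
                report.rows_quarantined += 1
                report.warn(f"record quarantined: {exc}")
                continue
            kept.append(row)
        # single stateful pass across all sources, so field values are shared
        rdfize_rows(kept, schema, rdfizer, graph)
        reports.append(report)
        log.info(f"rdfized {path.name}: {report.rows_emitted} records, {report.rows_quarantined} quarantined")

    stats = rdfizer.triple_reduction_stats()
    log.info(
        f"field-value triples: raw {stats['raw_field_value_triples']}, "
        f"deduplicated {stats['deduplicated_field_value_triples']}, "
        f"reduction {stats['percent_reduction']}%"
    )
    _mint_ontology_ids(graph, config, log)
    n_guards = apply_entity_typing(graph, config.entity_types, log)
    log.info(f"entity typing: {n_guards} denotesSubClassOf guard assertions")
    return graph, rdfizer, reports


def _mint_ontology_ids(graph: Graph, config: BuildConfig, log: BuildLog) -> int:
    """ICE identifiers for ontology concepts (records never hold BIO URIs)."""
    from rdflib.namespace import OWL

    from .namespaces import OBO

    added = 0
    for cls in sorted(graph.subjects(RDF.type, OWL.Class)):
        local = str(cls).replace(str(OBO), "")
        space, _, rest = local.partition("_")
        if space in config.ontology_id_spaces and rest:
            ice = URIRef(f"{KIAO}{local}_ICE")
            for t in (
                (ice, RDF.type, IDENTIFIER_ICE),
                (ice, CANONICAL_FORM, Literal(local)),
                (ice, IDENTIFIER_SPACE, Literal(space)),
                (ice, DENOTES, cls),
            ):
                if t not in graph:
                    graph.add(t)
                    added += 1
    log.info(f"ontology-concept ICE identifiers: {added} triples")
    return added


def _typed_universe(graph: Graph) -> List[URIRef]:
    return sorted(set(graph.subjects(DENOTES_SUBCLASS_OF, None)))


def run_build(config: BuildConfig, write_checkpoints: bool = True) -> BuildResult:
    """Run every stage in order; returns the complete in-memory result."""
    workdir = Path(config.workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    log = BuildLog(path=workdir / "build.log" if write_checkpoints else None)
    if log.path is not None and log.path.exists():
        log.path.unlink()
    derivations = DerivationIndex()
    stage_counts: Dict[str, int] = {}

    graph, rdfizer, reports = _rdfize_stage(config, log)
    stage_counts["rdfize"] = len(graph)
    if write_checkpoints:
        write_nt_gz(graph, workdir / STAGE_FILES["rdfize"])

    extraction = extract_exact_matches(graph, config.mapping_pairs, log)
    stage_counts["match-ids"] = len(graph) - stage_counts["rdfize"]
    if write_checkpoints:
        match_triples = [(e.left, NAMESPACES.expand("skos:exactMatch"), e.right) for e in extraction.edges]
        write_nt_gz(set(match_triples), workdir / STAGE_FILES["match-ids"])
        write_edges(extraction.edges, workdir / "edges.tsv")
    for edge in extraction.edges:
        derivations.add(
            DerivationRecord(
                triple=(edge.left, NAMESPACES.expand("skos:exactMatch"), edge.right),
                rule_name="exact-match-extraction",
                binding=(("left", edge.left), ("right", edge.right)),
                supporting_records=(edge.provenance_record,),
            )
        )

    id_sets = union_find_closure(extraction.edges, _typed_universe(graph))
    set_triples = []
    for idset in id_sets:
        set_triples.extend(materialize_id_set(idset))
    for t in set_triples:
        graph.add(t)
    stage_counts["merge-ids"] = len(set_triples)
    if write_checkpoints:
        write_nt_gz(set_triples, workdir / STAGE_FILES["merge-ids"])
    log.info(f"identifier sets: {len(id_sets)} sets, {len(set_triples)} membership triples")

    before_bio = len(graph)
    bio_entities: Dict[URIRef, URIRef] = {}
    for idset in id_sets:
        bio, triples = create_bio_entity(graph, idset)
        bio_entities[idset.uri] = bio
        for t in triples:
            graph.add(t)
    log.info(f"BIO entities: {len(bio_entities)} classes")

    rule_counts: Dict[str, int] = {}
    for batch_name in config.rule_batches:
        batch_path = Path(batch_name)
        if batch_path.exists():
            batch = load_rule_batch(batch_path)
        else:
            batch = bio_builder.load_builtin_batch(batch_name)
        counts = bio_builder.run_batch_to_fixpoint(batch, graph, derivations)
        rule_counts.update(counts)
        for rule, n in counts.items():
            log.info(f"rule {rule}: {n} new triples")
            if n == 0:
                log.info(f"WARNING rule {rule} produced zero triples (broken mapping?)")
    stage_counts["build-bio"] = len(graph) - before_bio
    rule_emitted = derivations.all_triples()
    if write_checkpoints:
        # checkpoint = everything added after the merge stage
        prior = _stage_union(workdir, "merge-ids")
        write_nt_gz((t for t in graph if t not in prior), workdir / STAGE_FILES["build-bio"])
        write_derivations(derivations, workdir / "derivations.tsv")
        _write_report(workdir, stage_counts, rule_counts, rdfizer, reports, id_sets)

    return BuildResult(
        graph=graph,
        derivations=derivations,
        id_sets=id_sets,
        edges=extraction.edges,
        parse_reports=reports,
        reduction_stats=rdfizer.triple_reduction_stats(),
        stage_counts=stage_counts,
        rule_counts=rule_counts,
        rule_emitted=rule_emitted,
        bio_entities=bio_entities,
        log=log,
    )


def _stage_union(workdir: Path, through: str) -> Graph:
    g = Graph()
    for stage in STAGE_ORDER:
        path = workdir / STAGE_FILES[stage]
        if path.exists():
            read_nt_gz(path, g)
        if stage == through:
            break
    return g


def require_stage(workdir: Path, stage: str) -> None:
    idx = STAGE_ORDER.index(stage)
    for prior in STAGE_ORDER[:idx]:
        if not (Path(workdir) / STAGE_FILES[prior]).exists():
            raise StageOrderViolation(f"stage {stage!r} requires {prior!r} output ({STAGE_FILES[prior]}) first")


def load_full_graph(workdir: Path) -> Graph:
    g = Graph()
    found = False
    for stage in STAGE_ORDER:
        path = Path(workdir) / STAGE_FILES[stage]
        if path.exists():
            read_nt_gz(path, g)
            found = True
    if not found:
        raise StageOrderViolation(f"no stage output found in {workdir}")
    return g


def id_sets_from_graph(graph: Graph) -> List[IdentifierSet]:
    sets: Dict[URIRef, List[URIRef]] = {}
    for s, _, o in graph.triples((None, HAS_MEMBER, None)):
        sets.setdefault(s, []).append(o)
    return sorted(
        (IdentifierSet(uri=u, members=tuple(sorted(m))) for u, m in sets.items()),
        key=lambda s: str(s.uri),
    )


def _write_report(workdir, stage_counts, rule_counts, rdfizer, reports, id_sets) -> None:
    lines = ["build report", "============"]
    for stage, n in stage_counts.items():
        lines.append(f"stage {stage}: {n} triples")
    lines.append(f"identifier sets: {len(id_sets)}")
    lines.append("per-rule emission counts:")
    for rule, n in sorted(rule_counts.items()):
        lines.append(f"  {rule}: {n}")
    stats = rdfizer.triple_reduction_stats()
    lines.append(
        f"field-value triples: raw {stats['raw_field_value_triples']}, "
        f"deduplicated {stats['deduplicated_field_value_triples']}, "
        f"reduction {stats['percent_reduction']}%"
    )
    for r in reports:
        lines.append(f"parse {Path(r.file).name}: read={r.rows_read} emitted={r.rows_emitted} quarantined={r.rows_quarantined}")
    (Path(workdir) / "report.txt").write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Quality control & demo query


def qc_from_result(result: BuildResult) -> List[QCFinding]:
    return run_qc(result.graph, result.id_sets, result.edges, DialectTable.builtin())


#: the demo retrieval as an ordered conjunctive pattern for the package's own
#: matcher (most selective patterns first; ``rdfs:subClassOf*`` patterns need
#: a bound subject). Block structure mirrors the case-study query: (A) things
#: localized to the mitochondrion and their participants, (B) the participant's
#: aggregate class, (D) a subclass of the aggregate participating in oxidative
#: phosphorylation, (E) interactions of the aggregate with a drug partner.
_DEMO_BODY = [
    # A
    ["?rl", "owl:someValuesFrom", "obo:GO_0005739"],
    ["?rl", "owl:onProperty", "obo:RO_0001025"],
    ["?loc", "rdfs:subClassOf", "?rl"],
    ["?loc", "rdfs:subClassOf*", "obo:GO_0051179"],
    ["?loc", "rdfs:subClassOf", "?rp"],
    ["?rp", "owl:onProperty", "obo:RO_0000057"],
    ["?rp", "owl:someValuesFrom", "?protein"],
    # B
    ["?protein", "rdfs:subClassOf", "?gorgpv"],
    # D
    ["?protein2", "rdfs:subClassOf", "?gorgpv"],
    ["?rp2", "owl:someValuesFrom", "?protein2"],
    ["?rp2", "owl:onProperty", "obo:RO_0000057"],
    ["?proc", "rdfs:subClassOf", "?rp2"],
    ["?proc", "rdfs:subClassOf*", "obo:GO_0006119"],
    # E
    ["?ri1", "owl:someValuesFrom", "?gorgpv"],
    ["?ri1", "owl:onProperty", "obo:RO_0000057"],
    ["?inter", "rdfs:subClassOf", "?ri1"],
    ["?inter", "rdfs:subClassOf", "obo:MI_0000"],
    ["?inter", "rdfs:subClassOf", "?ri2"],
    ["?ri2", "owl:onProperty", "obo:RO_0000057"],
    ["?ri2", "owl:someValuesFrom", "?drug"],
    ["?did", "obo:IAO_0000219", "?drug"],
    ["?did", "kiao:identifierSpace", '"DB"'],
    ["?did", "kiao:hasCanonicalForm", "?form"],
]


def demo_drug_query(graph: Graph) -> List[str]:
    """Fixture-scale version of the case-study retrieval: drugs interacting
    with genes whose products localize to the mitochondrion and participate
    in oxidative phosphorylation. Returns canonical drug identifier forms."""
    from .rule_engine import match, parse_term

    body = [tuple(parse_term(t) for t in pat) for pat in _DEMO_BODY]
    bindings = match(body, graph)
    return sorted({str(b["form"]) for b in bindings if b["ri1"] != b["ri2"]})
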