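"""Deterministic synthetic source-data generator.

Emulates, at desk scale, the kinds of inputs a biomedical integration build
consumes: a mini ontology (sequence types, a small process/component
hierarchy, two disjoint taxa, interaction and aboutness vocabulary), a gene
catalog with a mixed-type dbXref column, an identifier-mapping table whose
rows deliberately vary lexical dialects ("EG513" / "EG:513" / bare "513"), a
GAF 2.x annotation file, two overlapping drug–target sources, and a pathway
table. Identifier content is synthetic (no real accessions); the handful of
backbone ontology terms reuse genuine OBO ids so rules read naturally.

A ground-truth manifest — the identity partition, true annotations, planted
demo answer, and every planted error with the findings it must produce — is
written alongside, computed from the construction plan itself (never inferred
from pipeline output), so downstream checks are non-circular.

Identical (seed, counts, error plan) always produce byte-identical files.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import yaml

#: mini-ontology classes: (curie local, label, parent local or None)
_ONTOLOGY_CLASSES = [
    ("SO_0000110", "sequence_feature", None),
    ("SO_0000352", "DNA", "SO_0000110"),
    ("SO_0000704", "gene", "SO_0000352"),
    ("SO_0001217", "protein_coding_gene", "SO_0000704"),
    ("SO_0000336", "pseudogene", "SO_0000704"),
    ("SO_0000673", "transcript", "SO_0000110"),
    ("PR_000000001", "protein", None),
    ("GO_0008150", "biological_process", None),
    ("GO_0045333", "cellular_respiration", "GO_0008150"),
    ("GO_0006119", "oxidative_phosphorylation", "GO_0045333"),
    ("GO_0006096", "glycolytic_process", "GO_0008150"),
    ("GO_0006915", "apoptotic_process", "GO_0008150"),
    ("GO_0007049", "cell_cycle", "GO_0008150"),
    ("GO_0006810", "transport", "GO_0008150"),
    ("GO_0008380", "RNA_splicing", "GO_0008150"),
    ("GO_0006412", "translation", "GO_0008150"),
    ("GO_0016310", "phosphorylation", "GO_0008150"),
    ("GO_0051179", "localization", "GO_0008150"),
    ("GO_0005575", "cellular_component", None),
    ("GO_0005739", "mitochondrion", "GO_0005575"),
    ("GO_0005634", "nucleus", "GO_0005575"),
    ("GO_0005829", "cytosol", "GO_0005575"),
    ("GO_0005737", "cytoplasm", "GO_0005575"),
    ("GO_0005886", "plasma_membrane", "GO_0005575"),
    ("MI_0000", "molecular_interaction", None),
    ("CHEBI_23888", "drug", None),
    ("MONDO_0000001", "disease", None),
    ("IAO_0000030", "information_content_entity", None),
]

_ONTOLOGY_PROPERTIES = [
    ("RO_0000057", "has_participant"),
    ("RO_0002162", "in_taxon"),
    ("RO_0001025", "located_in"),
    ("IAO_0000219", "denotes"),
    ("IAO_0000142", "mentions"),
    ("IAO_0000136", "is_about"),
    ("BFO_0000051", "has_part"),
]

_BP_POOL = ["GO_0006096", "GO_0006915", "GO_0007049", "GO_0006810", "GO_0008380", "GO_0006412", "GO_0016310"]
_CC_POOL = ["GO_0005739", "GO_0005634", "GO_0005829", "GO_0005737", "GO_0005886"]
_OXPHOS = "GO_0006119"
_MITO = "GO_0005739"

OBO = "http://purl.obolibrary.org/obo/"


class FixtureError(ValueError):
    pass


@dataclass(frozen=True)
class ErrorPlan:
    """Planted source-data errors, known by construction."""

    cross_taxon_mapping: bool = True
    many_to_one_mapping: bool = True
    cross_type_dbxref: int = 2


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 1
    n_genes: int = 18
    n_drugs: int = 8
    n_pathways: int = 2
    taxa: Tuple[int, ...] = (10090, 10116)
    errors: ErrorPlan = field(default_factory=ErrorPlan)

    def __post_init__(self) -> None:
        if not self.taxa:
            raise FixtureError("at least one taxon is mandatory")
        if self.n_genes < 12 or self.n_drugs < 6:
            raise FixtureError("fixture needs at least 12 genes and 6 drugs")


# ---------------------------------------------------------------------------
# Construction plan (ground truth)


@dataclass
class _Gene:
    i: int
    eg: str
    hgnc: Optional[str]
    symbol: str
    taxon: int
    coding: bool
    up: Optional[str] = None
    pro: Optional[str] = None


@dataclass
class _Drug:
    d: int
    db: str
    pa: Optional[str]


def _plan(spec: FixtureSpec) -> Tuple[List[_Gene], List[_Drug]]:
    genes = []
    for i in range(spec.n_genes):
        coding = i % 5 != 4
        g = _Gene(
            i=i,
            eg=str(1000 + i),
            hgnc=str(500 + i) if i % 4 != 3 else None,
            symbol=f"G{i}",
            taxon=spec.taxa[i % len(spec.taxa)],
            coding=coding,
        )
        if coding:
            g.up = f"P{40000 + i}"
            g.pro = str(100000 + i) if i % 3 != 2 else None
        genes.append(g)
    drugs = [_Drug(d=d, db=f"{d + 1:05d}", pa=str(700 + d) if d % 2 == 0 else None) for d in range(spec.n_drugs)]
    return genes, drugs


def _planted_genes(genes: Sequence[_Gene]) -> List[_Gene]:
    """The demo answer genes: first three coding genes."""
    coding = [g for g in genes if g.coding]
    return coding[:3]


def _error_proteins(spec: FixtureSpec, genes: Sequence[_Gene]) -> Optional[Tuple[_Gene, _Gene]]:
    """Two non-planted coding genes in disjoint taxa for the cross-taxon error:
    the first lacking a PRO alias, the second carrying one."""
    if not spec.errors.cross_taxon_mapping or len(spec.taxa) < 2:
        return None
    planted = {g.i for g in _planted_genes(genes)}
    t0, t1 = spec.taxa[0], spec.taxa[1]
    a = next((g for g in genes if g.coding and g.i not in planted and g.taxon == t0 and g.pro is None), None)
    b = next((g for g in genes if g.coding and g.i not in planted and g.taxon == t1 and g.pro is not None), None)
    if a is None or b is None:
        raise FixtureError("counts too small to plant the cross-taxon error")
    return a, b


def _error_drugs(spec: FixtureSpec, drugs: Sequence[_Drug]) -> Optional[Tuple[_Drug, _Drug, str]]:
    """Two alias-less, non-answer drugs plus a fresh external accession for the
    many-to-one error."""
    if not spec.errors.many_to_one_mapping:
        return None
    candidates = [d for d in drugs if d.pa is None and d.d >= 3]
    if len(candidates) < 2:
        raise FixtureError("counts too small to plant the many-to-one error")
    return candidates[0], candidates[1], str(900 + spec.n_drugs)


# ---------------------------------------------------------------------------
# Ontology


def generate_mini_ontology(spec: FixtureSpec, path: Path) -> Path:
    """Write the mini ontology as sorted N-Triples (valid Turtle).

    All classes referenced by the shipped rules resolve here; the first two
    taxa are declared owl:disjointWith each other, which powers the
    disjoint-taxa quality check. Synthetic stand-in: only the handful of
    backbone terms reuse genuine OBO ids; the hierarchy is simplified.
    """
    rdf = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"
    rdfs = "http://www.w3.org/2000/01/rdf-schema#"
    owl = "http://www.w3.org/2002/07/owl#"
    lines = []

    def t(s: str, p: str, o: str) -> None:
        lines.append(f"<{s}> <{p}> {o} .")

    for local, label, parent in _ONTOLOGY_CLASSES:
        uri = OBO + local
        t(uri, rdf + "type", f"<{owl}Class>")
        t(uri, rdfs + "label", json.dumps(label))
        if parent:
            t(uri, rdfs + "subClassOf", f"<{OBO + parent}>")
    for n, taxon in enumerate(spec.taxa):
        uri = f"{OBO}NCBITaxon_{taxon}"
        t(uri, rdf + "type", f"<{owl}Class>")
        t(uri, rdfs + "label", json.dumps(f"taxon_{taxon}"))
        t(uri, rdfs + "subClassOf", f"<{OBO}NCBITaxon_1>")
    t(OBO + "NCBITaxon_1", rdf + "type", f"<{owl}Class>")
    t(OBO + "NCBITaxon_1", rdfs + "label", '"root_taxon"')
    if len(spec.taxa) >= 2:
        t(f"{OBO}NCBITaxon_{spec.taxa[0]}", owl + "disjointWith", f"<{OBO}NCBITaxon_{spec.taxa[1]}>")
    for local, label in _ONTOLOGY_PROPERTIES:
        uri = OBO + local
        t(uri, rdf + "type", f"<{owl}ObjectProperty>")
        t(uri, rdfs + "label", json.dumps(label))
    path.write_text("\n".join(sorted(set(lines))) + "\n")
    return path


# ---------------------------------------------------------------------------
# Source files


def _eg_dialect(local: str, i: int) -> str:
    return ["EG" + local, "EG:" + local, "EG_" + local][i % 3]


def _up_dialect(local: str, i: int) -> str:
    return ["UniProt:" + local, "UP:" + local, "UniProtKB:" + local][i % 3]


def generate_sources(spec: FixtureSpec, outdir: Path) -> Dict[str, Path]:
    """Write all mock source files, the build config, and the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = random.Random(spec.seed)
    genes, drugs = _plan(spec)
    planted = _planted_genes(genes)
    err_prot = _error_proteins(spec, genes)
    err_drug = _error_drugs(spec, drugs)

    paths: Dict[str, Path] = {}
    paths["ontology"] = generate_mini_ontology(spec, outdir / "mini_ontology.ttl")

    # --- gene catalog (NCBI-Gene-Info-like TSV with a mixed dbXref column)
    noisy = [g.i for g in genes if g.i not in {p.i for p in planted}][: spec.errors.cross_type_dbxref]
    rows = ["gene_id\tsymbol\ttaxon\tgene_type\tdbXref"]
    for g in genes:
        xrefs = []
        if g.hgnc:
            xrefs.append(f"HGNC:{g.hgnc}")
        if g.i in noisy:
            # deliberate cross-type cross-references: a disease and a drug id
            xrefs.append(f"OMIM:{600000 + g.i}")
            xrefs.append(f"DB{(g.i % spec.n_drugs) + 1:05d}")
        gene_id = [g.eg, "EG" + g.eg, "EG:" + g.eg][g.i % 3]  # bare form allowed: designated field
        gtype = "protein-coding" if g.coding else "ncRNA"
        rows.append(f"{gene_id}\t{g.symbol}\tNCBITaxon:{g.taxon}\t{gtype}\t{'|'.join(xrefs)}")
    paths["genecat"] = outdir / "gene_catalog.tsv"
    paths["genecat"].write_text("\n".join(rows) + "\n")

    # --- identifier mapping table (UniProt-idmapping-like, dialects varied)
    rows = ["from_id\tto_id\tmapping_type"]
    for g in genes:
        if g.up:
            rows.append(f"{_up_dialect(g.up, g.i)}\t{_eg_dialect(g.eg, g.i)}\tcoding")
        if g.up and g.pro:
            rows.append(f"{_up_dialect(g.up, g.i + 1)}\tPRO:{g.pro}\tprotein-alias")
    for d in drugs:
        if d.pa:
            rows.append(f"DrugBank:DB{d.db}\tPA{d.pa}\tdrug-alias")
    if err_prot:
        a, b = err_prot
        rows.append(f"{_up_dialect(a.up, 0)}\tPRO:{b.pro}\tprotein-alias")
    if err_drug:
        d1, d2, pa = err_drug
        rows.append(f"DrugBank:DB{d1.db}\tPA{pa}\tdrug-alias")
        rows.append(f"DrugBank:DB{d2.db}\tPA{pa}\tdrug-alias")
    paths["idmap"] = outdir / "id_mapping.tsv"
    paths["idmap"].write_text("\n".join(rows) + "\n")

    # --- GAF 2.x annotation file
    annotations: List[Tuple[str, str]] = []  # (UP local, GO local) ground truth
    gaf_lines = ["!gaf-version: 2.1", "! synthetic annotation fixture", "!"]
    evidence = ["IEA", "IDA", "IMP", "ISS"]

    def gaf_row(g: _Gene, go_local: str, aspect: str) -> str:
        ev = rng.choice(evidence)
        cols = [
            "UniProtKB",
            g.up,
            g.symbol,
            "",
            "GO:" + go_local.split("_")[1],
            f"PMID:{7000000 + g.i}",
            ev,
            "",
            aspect,
            f"{g.symbol} product",
            "",
            "protein",
            f"taxon:{g.taxon}",
            "20240101",
            "SYN",
            "",
            "",
        ]
        return "\t".join(cols)

    planted_idx = {p.i for p in planted}
    for g in genes:
        if not g.up:
            continue
        if g.i in planted_idx:
            bps = [_OXPHOS]
            ccs = [_MITO]
        else:
            bps = rng.sample(_BP_POOL, rng.randint(1, 2))
            ccs = [rng.choice(_CC_POOL)]
        for bp in bps:
            gaf_lines.append(gaf_row(g, bp, "P"))
            annotations.append((f"UP_{g.up}", bp))
        for cc in ccs:
            gaf_lines.append(gaf_row(g, cc, "C"))
            annotations.append((f"UP_{g.up}", cc))
    paths["goa"] = outdir / "annotations.gaf"
    paths["goa"].write_text("\n".join(gaf_lines) + "\n")

    # --- drug–target sources (two, with one shared interaction)
    answer_drugs = drugs[:3]
    rows = ["drug_id,gene_id"]
    pairs_a: List[Tuple[_Drug, _Gene]] = []
    for j, g in enumerate(planted):
        pairs_a.append((answer_drugs[j], g))
        pairs_a.append((answer_drugs[(j + 1) % 3], g))
    other_genes = [g for g in genes if g.coding and g.i not in planted_idx]
    for k, d in enumerate(drugs[3:]):
        if err_drug and d.d in (err_drug[0].d, err_drug[1].d) and not other_genes:
            continue
        pairs_a.append((d, other_genes[k % len(other_genes)]))
    for d, g in pairs_a:
        rows.append(f"DB{d.db},{_eg_dialect(g.eg, d.d)}")
    paths["drugbank"] = outdir / "drug_targets_a.csv"
    paths["drugbank"].write_text("\n".join(rows) + "\n")

    rows = ["drug_id\tgene_id"]
    # the first planted interaction again, through alias dialects: same
    # biomedical content from a second source
    d0, g0 = pairs_a[0]
    rows.append(f"{('PA' + d0.pa) if d0.pa else 'DB' + d0.db}\t{_eg_dialect(g0.eg, d0.d + 1)}")
    rows.append(f"DB{drugs[3].db}\t{_eg_dialect(other_genes[0].eg, 1)}")
    paths["pharmgkb"] = outdir / "drug_targets_b.tsv"
    paths["pharmgkb"].write_text("\n".join(rows) + "\n")

    # --- pathway table (multi-valued member column)
    rows = ["pathway_id\tprotein_ids"]
    coding = [g for g in genes if g.up]
    for p in range(spec.n_pathways):
        members = coding[p * 3 : p * 3 + 3] or coding[:3]
        rows.append(f"PW:{9001 + p}\t{'|'.join('UP:' + m.up for m in members)}")
    paths["pathway"] = outdir / "pathways.tsv"
    paths["pathway"].write_text("\n".join(rows) + "\n")

    # --- ground-truth manifest
    manifest = _manifest(spec, genes, drugs, planted, err_prot, err_drug, annotations, pairs_a)
    paths["manifest"] = outdir / "manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")

    # --- build configuration consumed by the pipeline / CLI
    paths["config"] = outdir / "build.yaml"
    paths["config"].write_text(yaml.safe_dump(build_config(spec), sort_keys=False))
    return paths


def _manifest(spec, genes, drugs, planted, err_prot, err_drug, annotations, pairs_a) -> Dict:
    partition: List[List[str]] = []
    for g in genes:
        group = [f"EG_{g.eg}"]
        if g.hgnc:
            group.append(f"HGNC_{g.hgnc}")
        partition.append(sorted(group))
    # protein groups, with the planted cross-taxon merge applied
    merged: Dict[int, List[str]] = {}
    for g in genes:
        if g.up:
            group = [f"UP_{g.up}"]
            if g.pro:
                group.append(f"PRO_{g.pro}")
            merged[g.i] = group
    expected_findings = {"disjoint-taxa": 0, "set-collision": 0, "many-to-one-mapping": 0}
    if err_prot:
        a, b = err_prot
        merged[a.i] = sorted(merged[a.i] + merged.pop(b.i))
        expected_findings["disjoint-taxa"] += 1
        expected_findings["set-collision"] += 1  # two UP ids in one set
        expected_findings["many-to-one-mapping"] += 1  # PRO id mapped from two records
    partition.extend(sorted(g) for g in merged.values())
    drug_groups: Dict[int, List[str]] = {}
    for d in drugs:
        group = [f"DB_{d.db}"]
        if d.pa:
            group.append(f"PA_{d.pa}")
        drug_groups[d.d] = group
    if err_drug:
        d1, d2, pa = err_drug
        drug_groups[d1.d] = sorted(drug_groups[d1.d] + drug_groups.pop(d2.d) + [f"PA_{pa}"])
        expected_findings["set-collision"] += 1  # two DB ids in one set
        expected_findings["many-to-one-mapping"] += 1  # the shared PA accession
    partition.extend(sorted(g) for g in drug_groups.values())
    for p in range(spec.n_pathways):
        partition.append([f"PW_{9001 + p}"])
    noisy = [g.i for g in genes if g.i not in {p.i for p in planted}][: spec.errors.cross_type_dbxref]
    for i in noisy:
        partition.append([f"OMIM_{600000 + i}"])
    answer = sorted({f"DB_{d.db}" for d, g in pairs_a if g.i in {p.i for p in planted}})
    return {
        "seed": spec.seed,
        "counts": {"genes": spec.n_genes, "drugs": spec.n_drugs, "pathways": spec.n_pathways},
        "partition": sorted(partition),
        "annotations": sorted(annotations),
        "coding_pairs": sorted([f"EG_{g.eg}", f"UP_{g.up}"] for g in genes if g.up),
        "planted_answer_drugs": answer,
        "planted_errors": {
            "cross_taxon_mapping": [f"UP_{err_prot[0].up}", f"PRO_{err_prot[1].pro}"] if err_prot else None,
            "many_to_one_mapping": [f"DB_{err_drug[0].db}", f"DB_{err_drug[1].db}", f"PA_{err_drug[2]}"]
            if err_drug
            else None,
            "cross_type_dbxref_genes": noisy,
        },
        "expected_findings": expected_findings,
    }


# ---------------------------------------------------------------------------
# Build configuration


def fixture_schemas() -> Dict[str, Dict]:
    """Schema configs for the generated source files."""
    return {
        "genecat": {
            "label": "genecat",
            "database": "gene-catalog",
            "delimiter": "\t",
            "fields": [
                {"name": "gene_id", "identifier_source": "EG", "primary_key": True},
                {"name": "symbol"},
                {"name": "taxon", "is_identifier": True},
                {"name": "gene_type"},
                {"name": "dbXref", "is_identifier": True, "mandatory": False},
            ],
        },
        "idmap": {
            "label": "idmap",
            "database": "id-mapping",
            "delimiter": "\t",
            "fields": [
                {"name": "from_id", "is_identifier": True, "primary_key": True},
                {"name": "to_id", "is_identifier": True, "primary_key": True},
                {"name": "mapping_type"},
            ],
        },
        "drugbank": {
            "label": "drugbank",
            "database": "drug-targets-a",
            "delimiter": ",",
            "fields": [
                {"name": "drug_id", "is_identifier": True, "primary_key": True},
                {"name": "gene_id", "is_identifier": True, "primary_key": True},
            ],
        },
        "pharmgkb": {
            "label": "pharmgkb",
            "database": "drug-targets-b",
            "delimiter": "\t",
            "fields": [
                {"name": "drug_id", "is_identifier": True, "primary_key": True},
                {"name": "gene_id", "is_identifier": True, "primary_key": True},
            ],
        },
        "pathway": {
            "label": "pathway",
            "database": "pathways",
            "delimiter": "\t",
            "fields": [
                {"name": "pathway_id", "identifier_source": "PW", "primary_key": True},
                {"name": "protein_ids", "is_identifier": True},
            ],
        },
    }


def entity_types() -> Dict[str, str]:
    """Identifier space → ontology class guard (the entity-typing assertions)."""
    return {
        "EG": "obo:SO_0000352",
        "HGNC": "obo:SO_0000704",
        "UP": "obo:PR_000000001",
        "PRO": "obo:PR_000000001",
        "DB": "obo:CHEBI_23888",
        "PA": "obo:CHEBI_23888",
        "PW": "obo:GO_0008150",
        "OMIM": "obo:MONDO_0000001",
    }


def build_config(spec: FixtureSpec) -> Dict:
    """The build.yaml contents for a fixture directory."""
    return {
        "seed": spec.seed,
        "ontologies": ["mini_ontology.ttl"],
        "ontology_id_spaces": ["GO", "NCBITaxon", "MI"],
        "sources": [
            {"path": "gene_catalog.tsv", "format": "delimited", "schema": "genecat"},
            {"path": "id_mapping.tsv", "format": "delimited", "schema": "idmap"},
            {"path": "annotations.gaf", "format": "gaf"},
            {"path": "drug_targets_a.csv", "format": "delimited", "schema": "drugbank"},
            {"path": "drug_targets_b.tsv", "format": "delimited", "schema": "pharmgkb"},
            {"path": "pathways.tsv", "format": "delimited", "schema": "pathway"},
        ],
        "schemas": fixture_schemas(),
        "entity_types": entity_types(),
        "mapping_pairs": [
            {"schema": "idmap", "left": "from_id", "right": "to_id"},
            {"schema": "genecat", "left": "gene_id", "right": "dbXref"},
        ],
        "rule_batches": ["40_taxon.yaml", "50_abstractions.yaml", "60_goa.yaml", "70_interactions.yaml", "80_pathway.yaml"],
    }
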