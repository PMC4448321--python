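"""Shared fixtures: one default synthetic build, reused across the suite."""

from __future__ import annotations

import json
from pathlib import Path

import pytest
from rdflib import Graph, Literal, URIRef
from rdflib.namespace import RDF, RDFS

from icebio import FixtureSpec, generate_sources
from icebio.fixtures import ErrorPlan
from icebio.namespaces import (
    DENOTES,
    HAS_IDENTIFIER,
    HAS_PART,
    HAS_TEMPLATE,
    KBIO,
    KIAO,
    OBO,
)
from icebio.pipeline import BuildConfig, BuildResult, run_build


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory) -> Path:
    """Default synthetic sources (seed 7), with the standard planted errors."""
    outdir = tmp_path_factory.mktemp("fixture")
    generate_sources(FixtureSpec(seed=7), outdir)
    return outdir


@pytest.fixture(scope="session")
def manifest(fixture_dir) -> dict:
    return json.loads((fixture_dir / "manifest.json").read_text())


@pytest.fixture(scope="session")
def build(fixture_dir) -> BuildResult:
    """A complete build of the default fixture, with checkpoints on disk."""
    config = BuildConfig.from_yaml(fixture_dir / "build.yaml")
    return run_build(config)


@pytest.fixture(scope="session")
def clean_build(tmp_path_factory):
    """A build of an error-free fixture (QC must report nothing)."""
    outdir = tmp_path_factory.mktemp("clean")
    generate_sources(
        FixtureSpec(seed=7, errors=ErrorPlan(False, False, 0)),
        outdir,
    )
    return run_build(BuildConfig.from_yaml(outdir / "build.yaml"))


def _identifier(graph: Graph, curie_local: str, space: str, denoted: URIRef | None = None) -> URIRef:
    from icebio.namespaces import CANONICAL_FORM, IDENTIFIER_ICE, IDENTIFIER_SPACE

    ident = URIRef(f"{KIAO}{curie_local}_ICE")
    graph.add((ident, RDF.type, IDENTIFIER_ICE))
    graph.add((ident, CANONICAL_FORM, Literal(curie_local)))
    graph.add((ident, IDENTIFIER_SPACE, Literal(space)))
    if denoted is not None:
        graph.add((ident, DENOTES, denoted))
    return ident


def _record(graph: Graph, schema: str, name: str, field_values: dict[str, URIRef]) -> URIRef:
    """A hand-built record ICE with one identifier-bearing field value per entry."""
    rec = URIRef(f"{KIAO}R_{name}")
    graph.add((rec, RDF.type, URIRef(f"{KIAO}Record_{schema}")))
    for field_name, ident in field_values.items():
        fv = URIRef(f"{KIAO}F_{schema}_{field_name}_{name}")
        graph.add((rec, HAS_PART, fv))
        graph.add((fv, HAS_TEMPLATE, URIRef(f"{KIAO}Field_{schema}_{field_name}")))
        graph.add((fv, HAS_IDENTIFIER, ident))
    return rec


@pytest.fixture
def goa_minimal():
    """Smallest graph the GO-annotation rule can fire on: one record, one
    protein identifier denoting a protein class, one GO identifier denoting a
    process class."""
    g = Graph()
    g.add((OBO.GO_0006119, RDFS.subClassOf, OBO.GO_0008150))
    protein = URIRef(f"{KBIO}BIO_protein1")
    pid = _identifier(g, "UP_P40000", "UP", protein)
    goid = _identifier(g, "GO_0006119", "GO", OBO.GO_0006119)
    rec = _record(g, "goa", "ann1", {"DB_Object_ID": pid, "GO_ID": goid})
    return g, rec, protein


@pytest.fixture
def interaction_minimal():
    """Smallest graph the drug–gene interaction rule can fire on."""
    g = Graph()
    drug = URIRef(f"{KBIO}BIO_drug1")
    gene = URIRef(f"{KBIO}BIO_gene1")
    did = _identifier(g, "DB_00001", "DB", drug)
    gid = _identifier(g, "EG_1000", "EG", gene)
    rec = _record(g, "drugbank", "int1", {"drug_id": did, "gene_id": gid})
    return g, rec, drug, gene


# re-exported builders for tests that want custom graphs
make_identifier = _identifier
make_record = _record
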