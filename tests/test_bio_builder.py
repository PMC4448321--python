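"""BIO-side patterns: five-triple annotations, nine-triple interactions,
aggregates, restriction reuse, conflict tolerance."""

from __future__ import annotations

import pytest
from rdflib import Graph, URIRef
from rdflib.namespace import OWL, RDF, RDFS

from icebio.bio_builder import (
    goa_rules,
    load_builtin_batch,
    multi_granularity_rules,
    orphan_proteins,
    restriction_census,
)
from icebio.namespaces import KBIO, KIAO, MENTIONS, OBO, partition_of
from icebio.rule_engine import apply_rule

from conftest import make_identifier, make_record


def goa_rule():
    return next(r for r in load_builtin_batch("60_goa.yaml").rules if r.name == "goa-process-participation")


def interaction_rule():
    batch = load_builtin_batch("70_interactions.yaml")
    return next(r for r in batch.rules if r.name == "drug-gene-interaction-src-a")


class TestGoaPattern:
    def test_fresh_binding_emits_exactly_five_concept_triples(self, goa_minimal):
        g, rec, protein = goa_minimal
        report = apply_rule(goa_rule(), g)
        assert report.bindings == 1
        assert report.new_concept_triples == 5
        assert report.new_mention_triples == 1  # record → generated class provenance

    def test_template_shape(self, goa_minimal):
        g, rec, protein = goa_minimal
        apply_rule(goa_rule(), g)
        restriction = next(g.subjects(RDF.type, OWL.Restriction))
        assert (restriction, OWL.onProperty, OBO.RO_0000057) in g
        assert (restriction, OWL.someValuesFrom, protein) in g
        new_process = next(g.subjects(RDFS.subClassOf, OBO.GO_0006119))
        assert (new_process, RDFS.subClassOf, restriction) in g

    def test_identical_binding_second_time_adds_nothing(self, goa_minimal):
        g, rec, protein = goa_minimal
        apply_rule(goa_rule(), g)
        report = apply_rule(goa_rule(), g)
        assert report.new_concept_triples == 0
        assert report.new_mention_triples == 0

    def test_restriction_reuse_three_new_triples(self, goa_minimal):
        """A second annotation of the same protein to a different process
        re-uses the participant restriction: 2 new subclass triples + 3-triple
        restriction already present → 2 concept triples, not 5."""
        g, rec, protein = goa_minimal
        g.add((OBO.GO_0006096, RDFS.subClassOf, OBO.GO_0008150))
        goid2 = make_identifier(g, "GO_0006096", "GO", OBO.GO_0006096)
        pid = next(s for s in g.subjects() if str(s).endswith("UP_P40000_ICE"))
        make_record(g, "goa", "ann2", {"DB_Object_ID": pid, "GO_ID": goid2})
        apply_rule(goa_rule(), g)
        # oracle: total concept triples = 2·(distinct bindings) + 3·(distinct restrictions)
        n_nodes, n_pairs = restriction_census(g)
        assert n_nodes == n_pairs == 1
        process_subclasses = {s for s in g.subjects(RDFS.subClassOf, None) if str(s).startswith(f"{KBIO}P_")}
        assert len(process_subclasses) == 2

    def test_counting_oracle_on_overlapping_annotations(self):
        """20 annotations with overlapping participants: new concept triples
        equal 2·distinct(protein, process) + 3·distinct restrictions."""
        g = Graph()
        processes = [OBO.GO_0006096, OBO.GO_0006915, OBO.GO_0007049]
        for p in processes:
            g.add((p, RDFS.subClassOf, OBO.GO_0008150))
        proteins, goids, pids = [], {}, {}
        for i in range(4):
            proteins.append(URIRef(f"{KBIO}BIO_prot{i}"))
            pids[i] = make_identifier(g, f"UP_P5000{i}", "UP", proteins[i])
        for j, p in enumerate(processes):
            goids[j] = make_identifier(g, f"GO_000{j}", "GO", p)
        bindings = set()
        for k in range(20):
            i, j = k % 4, (k * 7) % 3
            make_record(g, "goa", f"a{k}", {"DB_Object_ID": pids[i], "GO_ID": goids[j]})
            bindings.add((proteins[i], processes[j]))
        report = apply_rule(goa_rule(), g)
        distinct_restrictions = len({prot for prot, _ in bindings})
        assert report.new_concept_triples == 2 * len(bindings) + 3 * distinct_restrictions


class TestInteractionPattern:
    def test_first_occurrence_emits_exactly_nine_triples(self, interaction_minimal):
        g, rec, drug, gene = interaction_minimal
        report = apply_rule(interaction_rule(), g)
        assert report.bindings == 1
        assert report.new_concept_triples == 9
        assert report.new_mention_triples == 1

    def test_shape_two_restrictions_and_interaction_subclass(self, interaction_minimal):
        g, rec, drug, gene = interaction_minimal
        apply_rule(interaction_rule(), g)
        inter = next(g.subjects(RDFS.subClassOf, OBO.MI_0000))
        restrictions = [o for o in g.objects(inter, RDFS.subClassOf) if o != OBO.MI_0000]
        assert len(restrictions) == 2
        fillers = {next(g.objects(r, OWL.someValuesFrom)) for r in restrictions}
        assert drug in fillers

    def test_same_pair_from_second_source_adds_zero_concept_triples(self, interaction_minimal):
        """Two sources of the same information lead to the same biomedical
        modeling: identical hash-minted URIs, exact triple-set equality."""
        g, rec, drug, gene = interaction_minimal
        apply_rule(interaction_rule(), g)

        def bio_triples():
            return {t for t in g if partition_of(t[0]) == "bio" and t[1] != MENTIONS}

        first_source = bio_triples()
        did = next(s for s in g.subjects() if str(s).endswith("DB_00001_ICE"))
        gid = next(s for s in g.subjects() if str(s).endswith("EG_1000_ICE"))
        make_record(g, "pharmgkb", "int2", {"drug_id": did, "gene_id": gid})
        batch = load_builtin_batch("70_interactions.yaml")
        rule_b = next(r for r in batch.rules if r.name == "drug-gene-interaction-src-b")
        report = apply_rule(rule_b, g)
        assert report.new_concept_triples == 0
        assert report.new_mention_triples == 1
        assert bio_triples() == first_source  # exact triple-set equality

    def test_restriction_count_equals_distinct_pairs_fixture(self, build):
        """Graph-wide: restriction nodes = distinct (property, filler) pairs."""
        n_nodes, n_pairs = restriction_census(build.graph)
        assert n_nodes == n_pairs > 0


class TestAbstractions:
    def test_aggregate_membership_arithmetic(self, build):
        """Arithmetic oracle over the full build: every gene class is a direct
        subclass of its two aggregates; every templated protein joins both."""
        g = build.graph
        genes = {s for s in g.subjects(RDFS.subClassOf, None) if _is_agg(g, s, "GorGP_BIO_")}
        from icebio.namespaces import INDIRECTLY_TEMPLATES

        coding = list(g.triples((None, INDIRECTLY_TEMPLATES, None)))
        assert coding, "fixture must contain coding links"
        for gene, _, protein in coding:
            gorgp = [o for o in g.objects(gene, RDFS.subClassOf) if str(o).startswith(f"{KBIO}GorGP_BIO_")]
            assert len(gorgp) == 1
            assert (protein, RDFS.subClassOf, gorgp[0]) in g

    def test_gene_without_product_still_gets_aggregates(self, build):
        g = build.graph
        from icebio.namespaces import INDIRECTLY_TEMPLATES

        templated = set(g.subjects(INDIRECTLY_TEMPLATES, None))
        all_genes = {
            s
            for s in g.subjects(RDFS.subClassOf, None)
            if any(str(o).startswith(f"{KBIO}GorGP_BIO_") for o in g.objects(s, RDFS.subClassOf))
            and str(s).startswith(f"{KBIO}BIO_")
        }
        solo = all_genes - templated
        assert solo, "fixture includes non-coding genes"

    def test_no_unionof_emitted(self, build):
        assert not list(build.graph.triples((None, OWL.unionOf, None)))

    def test_orphan_census_runs(self, build):
        assert isinstance(orphan_proteins(build.graph), list)


def _is_agg(g, s, prefix):
    return any(str(o).startswith(f"{KBIO}{prefix}") for o in g.objects(s, RDFS.subClassOf))


class TestPathwayGranularity:
    def test_pathway_with_three_proteins(self):
        g = Graph()
        pathway = URIRef(f"{KBIO}BIO_pw1")
        wid = make_identifier(g, "PW_9001", "PW", pathway)
        proteins = [URIRef(f"{KBIO}BIO_p{i}") for i in range(3)]
        fvs = {}
        for i, p in enumerate(proteins):
            fvs[f"x{i}"] = make_identifier(g, f"UP_P600{i}", "UP", p)
        rec = make_record(g, "pathway", "pw1", {"pathway_id": wid})
        from icebio.namespaces import HAS_IDENTIFIER, HAS_PART, HAS_TEMPLATE

        for i, ident in enumerate(fvs.values()):
            fv = URIRef(f"{KIAO}F_pathway_protein_ids_y{i}")
            g.add((rec, HAS_PART, fv))
            g.add((fv, HAS_TEMPLATE, URIRef(f"{KIAO}Field_pathway_protein_ids")))
            g.add((fv, HAS_IDENTIFIER, ident))
        multi_granularity_rules(g)
        subclasses = {s for s in g.subjects(RDFS.subClassOf, pathway)}
        assert len(subclasses) == 1
        n_nodes, _ = restriction_census(g)
        assert n_nodes == 3

    def test_empty_pathway_no_emission(self):
        g = Graph()
        pathway = URIRef(f"{KBIO}BIO_pw2")
        wid = make_identifier(g, "PW_9002", "PW", pathway)
        make_record(g, "pathway", "pw2", {"pathway_id": wid})
        counts = multi_granularity_rules(g)
        assert counts["pathway-participants"] == 0

    def test_coarse_and_fine_rules_coexist(self, build):
        """Coarse pathway and fine GO-participation rules over the same
        proteins: the union contains both patterns, nothing removed."""
        g = build.graph
        coarse = {s for s in g.subjects(RDFS.subClassOf, None) if str(s).startswith(f"{KBIO}PW_")}
        fine = {s for s in g.subjects(RDFS.subClassOf, None) if str(s).startswith(f"{KBIO}P_")}
        assert coarse and fine


class TestConflictTolerance:
    def test_contradictory_records_yield_independent_subclasses(self):
        """The same protein annotated to two different processes never merges
        or deletes anything: two independent generated subclasses."""
        g = Graph()
        for p in (OBO.GO_0006096, OBO.GO_0006915):
            g.add((p, RDFS.subClassOf, OBO.GO_0008150))
        protein = URIRef(f"{KBIO}BIO_protX")
        pid = make_identifier(g, "UP_P7000", "UP", protein)
        a = make_identifier(g, "GO_0006096", "GO", OBO.GO_0006096)
        b = make_identifier(g, "GO_0006915", "GO", OBO.GO_0006915)
        make_record(g, "goa", "c1", {"DB_Object_ID": pid, "GO_ID": a})
        make_record(g, "goa", "c2", {"DB_Object_ID": pid, "GO_ID": b})
        before = set(g)
        goa_rules(g)
        assert before <= set(g)  # monotone
        generated = {s for s in g.subjects(RDFS.subClassOf, None) if str(s).startswith(f"{KBIO}P_")}
        assert len(generated) == 2


def test_no_rule_asserts_on_imported_ontology_classes(build):
    """Every generated assertion introduces a fresh subclass: no rule-emitted
    triple has an imported ontology class as its subject."""
    for triple in build.rule_emitted:
        assert partition_of(triple[0]) != "onto", triple
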