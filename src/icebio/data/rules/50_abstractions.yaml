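# Sequence-abstraction layers: for every gene class, aggregate
# gene-or-gene-product and gene-or-gene-product-or-variant classes, encoded as
# plain superclasses (parallel-superclass encoding, no owl:unionOf, keeping
# the graph within the OWL-EL profile). Cross-type mapping records (protein id
# paired with gene id) drive the gene→protein indirect-template link and the
# protein's membership in the gene's aggregates.
batch: abstractions
rules:
  - name: gene-aggregates
    body:
      - ["?gid", "kiao:denotesSubClassOf", "?t"]
      - ["?t", "rdfs:subClassOf*", "obo:SO_0000352"]
      - ["?gid", "obo:IAO_0000219", "?gene"]
    mint:
      gorgp: {kind: bio-class, components: ["gorgp", "?gene"], uri_prefix: "GorGP_BIO_"}
      gorgpv: {kind: bio-class, components: ["gorgpv", "?gene"], uri_prefix: "GorGPorV_BIO_"}
    head:
      - ["?gene", "rdfs:subClassOf", "?gorgp"]
      - ["?gene", "rdfs:subClassOf", "?gorgpv"]
      - ["?gorgp", "rdfs:subClassOf", "?gorgpv"]
  - name: gene-product-links
    record_vars: [r]
    body:
      - ["?r", "rdf:type", "kiao:Record_idmap"]
      - ["?r", "obo:BFO_0000051", "?pfv"]
      - ["?pfv", "kiao:hasTemplate", "kiao:Field_idmap_from_id"]
      - ["?pfv", "kiao:hasIdentifier", "?pid"]
      - ["?pid", "kiao:denotesSubClassOf", "?pt"]
      - ["?pt", "rdfs:subClassOf*", "obo:PR_000000001"]
      - ["?pid", "obo:IAO_0000219", "?protein"]
      - ["?r", "obo:BFO_0000051", "?gfv"]
      - ["?gfv", "kiao:hasTemplate", "kiao:Field_idmap_to_id"]
      - ["?gfv", "kiao:hasIdentifier", "?gid"]
      - ["?gid", "kiao:denotesSubClassOf", "?gt"]
      - ["?gt", "rdfs:subClassOf*", "obo:SO_0000352"]
      - ["?gid", "obo:IAO_0000219", "?gene"]
    mint:
      gorgp: {kind: bio-class, components: ["gorgp", "?gene"], uri_prefix: "GorGP_BIO_"}
      gorgpv: {kind: bio-class, components: ["gorgpv", "?gene"], uri_prefix: "GorGPorV_BIO_"}
    head:
      - ["?gene", "kro:indirectlyTemplates", "?protein"]
      - ["?protein", "rdfs:subClassOf", "?gorgp"]
      - ["?protein", "rdfs:subClassOf", "?gorgpv"]
    mentions:
      - {from: "?r", to: "?gorgp"}
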