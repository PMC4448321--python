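# Drug–gene interaction rules: nine triples at first occurrence — two
# all-some participant restrictions (three triples each) and an interaction
# subclass with three subclass triples. The target participant is the gene's
# gene-or-gene-product-or-variant aggregate, since drug sources rarely say
# whether the drug binds the gene, a product, or a variant. Restriction and
# interaction URIs are pure hashes of their defining values, so a second
# source reporting the same pair adds zero new triples.
batch: interactions
rules:
  - name: drug-gene-interaction-src-a
    record_vars: [r]
    body:
      - ["?r", "rdf:type", "kiao:Record_drugbank"]
      - ["?r", "obo:BFO_0000051", "?dfv"]
      - ["?dfv", "kiao:hasTemplate", "kiao:Field_drugbank_drug_id"]
      - ["?dfv", "kiao:hasIdentifier", "?did"]
      - ["?did", "obo:IAO_0000219", "?drug"]
      - ["?r", "obo:BFO_0000051", "?gfv"]
      - ["?gfv", "kiao:hasTemplate", "kiao:Field_drugbank_gene_id"]
      - ["?gfv", "kiao:hasIdentifier", "?gid"]
      - ["?gid", "obo:IAO_0000219", "?gene"]
    mint:
      gorgpv: {kind: bio-class, components: ["gorgpv", "?gene"], uri_prefix: "GorGPorV_BIO_"}
      rtarget: {kind: restriction, components: ["obo:RO_0000057", "?gorgpv"]}
      rdrug: {kind: restriction, components: ["obo:RO_0000057", "?drug"]}
      inter: {kind: bio-class, components: ["int", "obo:MI_0000", "?drug", "?gorgpv"], uri_prefix: "I_"}
    head:
      - ["?rtarget", "rdf:type", "owl:Restriction"]
      - ["?rtarget", "owl:onProperty", "obo:RO_0000057"]
      - ["?rtarget", "owl:someValuesFrom", "?gorgpv"]
      - ["?rdrug", "rdf:type", "owl:Restriction"]
      - ["?rdrug", "owl:onProperty", "obo:RO_0000057"]
      - ["?rdrug", "owl:someValuesFrom", "?drug"]
      - ["?inter", "rdfs:subClassOf", "obo:MI_0000"]
      - ["?inter", "rdfs:subClassOf", "?rtarget"]
      - ["?inter", "rdfs:subClassOf", "?rdrug"]
    mentions:
      - {from: "?r", to: "?inter"}
  - name: drug-gene-interaction-src-b
    record_vars: [r]
    body:
      - ["?r", "rdf:type", "kiao:Record_pharmgkb"]
      - ["?r", "obo:BFO_0000051", "?dfv"]
      - ["?dfv", "kiao:hasTemplate", "kiao:Field_pharmgkb_drug_id"]
      - ["?dfv", "kiao:hasIdentifier", "?did"]
      - ["?did", "obo:IAO_0000219", "?drug"]
      - ["?r", "obo:BFO_0000051", "?gfv"]
      - ["?gfv", "kiao:hasTemplate", "kiao:Field_pharmgkb_gene_id"]
      - ["?gfv", "kiao:hasIdentifier", "?gid"]
      - ["?gid", "obo:IAO_0000219", "?gene"]
    mint:
      gorgpv: {kind: bio-class, components: ["gorgpv", "?gene"], uri_prefix: "GorGPorV_BIO_"}
      rtarget: {kind: restriction, components: ["obo:RO_0000057", "?gorgpv"]}
      rdrug: {kind: restriction, components: ["obo:RO_0000057", "?drug"]}
      inter: {kind: bio-class, components: ["int", "obo:MI_0000", "?drug", "?gorgpv"], uri_prefix: "I_"}
    head:
      - ["?rtarget", "rdf:type", "owl:Restriction"]
      - ["?rtarget", "owl:onProperty", "obo:RO_0000057"]
      - ["?rtarget", "owl:someValuesFrom", "?gorgpv"]
      - ["?rdrug", "rdf:type", "owl:Restriction"]
      - ["?rdrug", "owl:onProperty", "obo:RO_0000057"]
      - ["?rdrug", "owl:someValuesFrom", "?drug"]
      - ["?inter", "rdfs:subClassOf", "obo:MI_0000"]
      - ["?inter", "rdfs:subClassOf", "?rtarget"]
      - ["?inter", "rdfs:subClassOf", "?rdrug"]
    mentions:
      - {from: "?r", to: "?inter"}
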