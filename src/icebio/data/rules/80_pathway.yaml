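# Coarse-grained pathway representation: a pathway that has_participant its
# member proteins. Finer-grained rules over the same records (e.g. the GO
# process-participation rule) coexist without conflict: rules only add
# triples, and each assertion lives in its own generated subclass.
batch: pathway
rules:
  - name: pathway-participants
    record_vars: [r]
    body:
      - ["?r", "rdf:type", "kiao:Record_pathway"]
      - ["?r", "obo:BFO_0000051", "?wfv"]
      - ["?wfv", "kiao:hasTemplate", "kiao:Field_pathway_pathway_id"]
      - ["?wfv", "kiao:hasIdentifier", "?wid"]
      - ["?wid", "obo:IAO_0000219", "?pathway"]
      - ["?r", "obo:BFO_0000051", "?pfv"]
      - ["?pfv", "kiao:hasTemplate", "kiao:Field_pathway_protein_ids"]
      - ["?pfv", "kiao:hasIdentifier", "?pid"]
      - ["?pid", "obo:IAO_0000219", "?protein"]
    mint:
      participant: {kind: restriction, components: ["obo:RO_0000057", "?protein"]}
      pwsub: {kind: bio-class, components: ["pathway", "?pathway"], uri_prefix: "PW_"}
    head:
      - ["?pwsub", "rdfs:subClassOf", "?pathway"]
      - ["?participant", "rdf:type", "owl:Restriction"]
      - ["?participant", "owl:onProperty", "obo:RO_0000057"]
      - ["?participant", "owl:someValuesFrom", "?protein"]
      - ["?pwsub", "rdfs:subClassOf", "?participant"]
    mentions:
      - {from: "?r", to: "?pwsub"}
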