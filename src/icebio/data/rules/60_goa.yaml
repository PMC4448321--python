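# GO-annotation rules. The biological-process rule instantiates the
# five-triple all-some template: a fresh process class, subclass of the
# annotated GO process, carrying a has_participant someValuesFrom restriction
# on the annotated protein. The cellular-component rule models the annotation
# as a localization subclass with participant and located_in restrictions.
batch: goa
rules:
  - name: goa-process-participation
    record_vars: [r]
    body:
      - ["?r", "rdf:type", "kiao:Record_goa"]
      - ["?r", "obo:BFO_0000051", "?pfv"]
      - ["?pfv", "kiao:hasTemplate", "kiao:Field_goa_DB_Object_ID"]
      - ["?pfv", "kiao:hasIdentifier", "?pid"]
      - ["?pid", "obo:IAO_0000219", "?protein"]
      - ["?r", "obo:BFO_0000051", "?gfv"]
      - ["?gfv", "kiao:hasTemplate", "kiao:Field_goa_GO_ID"]
      - ["?gfv", "kiao:hasIdentifier", "?goid"]
      - ["?goid", "obo:IAO_0000219", "?goProcess"]
      - ["?goProcess", "rdfs:subClassOf*", "obo:GO_0008150"]
    mint:
      participant: {kind: restriction, components: ["obo:RO_0000057", "?protein"]}
      newProcess: {kind: bio-class, components: ["goa", "?goProcess", "?protein"], uri_prefix: "P_"}
    head:
      - ["?newProcess", "rdfs:subClassOf", "?goProcess"]
      - ["?participant", "rdf:type", "owl:Restriction"]
      - ["?participant", "owl:onProperty", "obo:RO_0000057"]
      - ["?participant", "owl:someValuesFrom", "?protein"]
      - ["?newProcess", "rdfs:subClassOf", "?participant"]
    mentions:
      - {from: "?r", to: "?newProcess"}
  - name: goa-component-localization
    record_vars: [r]
    body:
      - ["?r", "rdf:type", "kiao:Record_goa"]
      - ["?r", "obo:BFO_0000051", "?pfv"]
      - ["?pfv", "kiao:hasTemplate", "kiao:Field_goa_DB_Object_ID"]
      - ["?pfv", "kiao:hasIdentifier", "?pid"]
      - ["?pid", "obo:IAO_0000219", "?protein"]
      - ["?r", "obo:BFO_0000051", "?gfv"]
      - ["?gfv", "kiao:hasTemplate", "kiao:Field_goa_GO_ID"]
      - ["?gfv", "kiao:hasIdentifier", "?goid"]
      - ["?goid", "obo:IAO_0000219", "?component"]
      - ["?component", "rdfs:subClassOf*", "obo:GO_0005575"]
    mint:
      participant: {kind: restriction, components: ["obo:RO_0000057", "?protein"]}
      location: {kind: restriction, components: ["obo:RO_0001025", "?component"]}
      newLoc: {kind: bio-class, components: ["loc", "?component", "?protein"], uri_prefix: "L_"}
    head:
      - ["?newLoc", "rdfs:subClassOf", "obo:GO_0051179"]
      - ["?participant", "rdf:type", "owl:Restriction"]
      - ["?participant", "owl:onProperty", "obo:RO_0000057"]
      - ["?participant", "owl:someValuesFrom", "?protein"]
      - ["?newLoc", "rdfs:subClassOf", "?participant"]
      - ["?location", "rdf:type", "owl:Restriction"]
      - ["?location", "owl:onProperty", "obo:RO_0001025"]
      - ["?location", "owl:someValuesFrom", "?component"]
      - ["?newLoc", "rdfs:subClassOf", "?location"]
    mentions:
      - {from: "?r", to: "?newLoc"}
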