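# Species links: BIO entities carry an in_taxon edge derived from the taxon
# field of the source record that mentions them (needed by the disjoint-taxa
# quality check).
batch: taxon
rules:
  - name: gene-taxon
    record_vars: [r]
    body:
      - ["?r", "rdf:type", "kiao:Record_genecat"]
      - ["?r", "obo:BFO_0000051", "?gfv"]
      - ["?gfv", "kiao:hasTemplate", "kiao:Field_genecat_gene_id"]
      - ["?gfv", "kiao:hasIdentifier", "?gid"]
      - ["?gid", "obo:IAO_0000219", "?gene"]
      - ["?r", "obo:BFO_0000051", "?tfv"]
      - ["?tfv", "kiao:hasTemplate", "kiao:Field_genecat_taxon"]
      - ["?tfv", "kiao:hasIdentifier", "?tid"]
      - ["?tid", "obo:IAO_0000219", "?taxon"]
    head:
      - ["?gene", "obo:RO_0002162", "?taxon"]
  - name: protein-taxon
    record_vars: [r]
    body:
      - ["?r", "rdf:type", "kiao:Record_goa"]
      - ["?r", "obo:BFO_0000051", "?pfv"]
      - ["?pfv", "kiao:hasTemplate", "kiao:Field_goa_DB_Object_ID"]
      - ["?pfv", "kiao:hasIdentifier", "?pid"]
      - ["?pid", "obo:IAO_0000219", "?protein"]
      - ["?r", "obo:BFO_0000051", "?tfv"]
      - ["?tfv", "kiao:hasTemplate", "kiao:Field_goa_Taxon"]
      - ["?tfv", "kiao:hasIdentifier", "?tid"]
      - ["?tid", "obo:IAO_0000219", "?taxon"]
    head:
      - ["?protein", "obo:RO_0002162", "?taxon"]
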