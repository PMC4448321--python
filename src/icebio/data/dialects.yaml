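# Identifier dialect rules: lexical variants of each identifier space and the
# canonical prefix they normalize to. `patterns` apply in any field context;
# `bare_patterns` apply only in a field designated to contain that source's
# identifiers. New sources add entries here, not code.
dialects:
  - source: EG                 # NCBI-Gene-style numeric gene identifiers
    canonical_prefix: EG
    patterns:
      - "EG[:_]?(?P<local>[0-9]+)"
      - "GeneID:(?P<local>[0-9]+)"
    bare_patterns:
      - "(?P<local>[0-9]+)"
  - source: HGNC               # gene-nomenclature identifiers
    canonical_prefix: HGNC
    patterns:
      - "HGNC[:_]?(?P<local>[0-9]+)"
    bare_patterns:
      - "(?P<local>[0-9]+)"
  - source: UP                 # UniProt-style protein accessions
    canonical_prefix: UP
    patterns:
      - "(?:UniProtKB|UniProt|UP)[:_](?P<local>[A-Z][0-9][A-Z0-9]{3,8}[0-9])"
    bare_patterns:
      - "(?P<local>[A-Z][0-9][A-Z0-9]{3,8}[0-9])"
  - source: PRO                # second protein identifier space
    canonical_prefix: PRO
    patterns:
      - "PRO[:_](?P<local>[0-9]{6,9})"
    bare_patterns:
      - "(?P<local>[0-9]{6,9})"
  - source: GO                 # ontology process / component identifiers
    canonical_prefix: GO
    patterns:
      - "GO[:_](?P<local>[0-9]{7})"
  - source: NCBITaxon
    canonical_prefix: NCBITaxon
    patterns:
      - "(?:NCBITaxon|taxon|NCBI_TaxID)[:_](?P<local>[0-9]+)"
  - source: MI                 # interaction-type identifiers
    canonical_prefix: MI
    patterns:
      - "MI[:_](?P<local>[0-9]{4})"
  - source: DB                 # DrugBank-style drug identifiers
    canonical_prefix: DB
    patterns:
      - "(?:DrugBank:)?DB(?P<local>[0-9]{5})"
  - source: PA                 # PharmGKB-style accessions
    canonical_prefix: PA
    patterns:
      - "(?:PharmGKB:)?PA(?P<local>[0-9]+)"
  - source: PW                 # pathway identifiers
    canonical_prefix: PW
    patterns:
      - "PW[:_]?(?P<local>[0-9]+)"
  - source: OMIM               # disease identifiers (dbXref noise)
    canonical_prefix: OMIM
    patterns:
      - "(?:OMIM|MIM)[:_]?(?P<local>[0-9]{6})"
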