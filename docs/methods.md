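# Methods

This note documents the modeling conventions, numerical choices, and known
limitations of `icebio`. It is the package's account of *why* the graph looks
the way it does; the README shows *how* to produce it.

## Informational entities vs. biomedical concepts

The central commitment is the strict separation of information content
entities (ICE: databases, schemas, records, fields, field values,
identifiers) from the biomedical concepts they describe (BIO: genes,
proteins, processes, interactions). A UniProt-style accession, the record it
appears in, and the protein class it denotes are three distinct nodes. The
separation buys three things: source data remain queryable even before any
biomedical mapping exists; the ICE layer doubles as provenance for every BIO
assertion; and inconsistent sources cannot corrupt the biomedical layer,
because each source assertion lands in its own generated subclass.

Three URI regions implement the separation (`kiao:` for ICE, `kbio:` for BIO,
OBO PURLs for imported vocabulary). The partition checker treats imported
ontology classes as a third region: the only predicates allowed from an ICE
subject to a `kbio:` object are the aboutness relations `iao:denotes`,
`iao:mentions`, `iao:is_about`. The bootstrap typing relation
`kiao:denotesSubClassOf` points from identifier ICEs to *ontology* classes;
it is a macrorelation equivalent to a denotes∘subClassOf chain, and its
entailment is realized at the identifier-set stage, where each set's single
BIO class is subClassOf the guard class and every member denotes it. The
standalone expansion operation (one assertion → two triples with a
deterministic intermediate) is available in the rule engine for rule authors
who need a per-identifier denotation.

## Deterministic URI minting

Every generated node is a URI whose token is the URL-safe base64 encoding
(padding stripped; always 27 characters) of a SHA-1 digest. The hashed bytes
are UTF-8 of `"<kind-tag>|"` followed by the pipe-joined components of the
entity, with `%`/`|` percent-escaped inside components. Kind tags (`fv`
field values, `rec` records, `ids` identifier sets, `rst` restrictions, `bio`
generated classes) make cross-kind collisions impossible; generated-class
payloads additionally start with a pattern tag (`set`, `gorgp`, `goa`, `int`,
…) so distinct rules never collide. Components per kind:

| kind | components |
|---|---|
| field value | schema label, field name, value (canonical URI for identifier fields) |
| record | schema URI, primary-key values (all fields when no key is declared) |
| identifier set | member URIs, lexicographically sorted |
| restriction | property URI, filler URI |
| generated class | pattern tag, then its defining inputs (e.g. `goa`, process, protein) |

Set URIs are therefore permutation-invariant; restriction URIs are pure
functions of (property, filler), which makes the graph-wide restriction count
equal the number of distinct such pairs (asserted in tests). SHA-1 is a
deliberate choice: the URIs need stability and uniqueness, not cryptographic
security, and 160 bits is ample at any realistic scale.

The exact byte serialization is this package's own convention. It is
documented here precisely because nothing else pins it down: a validation
experiment confirmed the encoding (the empty payload yields
`2jmj7l5rSw0yVb_vlWAYkK_YBwk`) but showed that no plausible field/value
serialization is universal across implementations of this idea, so exact
token values should never be compared across systems — only *within* builds,
where determinism is what matters.

## Record representation and field-value sharing

A record ICE carries `rdf:type` (per-schema record class) and
`kiao:hasTemplate` (its schema), plus one `obo:has_part` per populated field
value — the record-centric direction. Every field-value node is defined by
exactly three triples: its type (per-schema field-value class), its
`kiao:hasTemplate` to the field ICE, and one value triple. For plain fields
the value triple is a literal (`kiao:hasLiteralValue`, kept as the source
bytes; numeric typing is left to rules). For identifier-bearing fields it is
`kiao:hasIdentifier` pointing at the globally shared canonical identifier
ICE, which itself carries exactly three defining triples (type, canonical
lexical form, identifier space). This two-node arrangement keeps the
three-triple invariant while letting one identifier appear in any number of
fields across sources under a single URI. Empty-string values mint nothing
(absence is safer than a vacuous node); multi-valued cells are
pipe-separated. Records with no declared key are minted from all field
values, so exact duplicate rows collapse to one record node.

Sharing is what pays for the explicitness: in the default synthetic build the
three-triples-per-occurrence accounting drops ~57% through node reuse. The
figure is a property of the fixture's duplication structure, not a universal
constant, and is recomputed in the build report every run.

## Identifier canonicalization

Dialect rules live in a declarative YAML table (`data/dialects.yaml`), one
entry per identifier space: full-match regexes that apply anywhere, and
bare-form regexes that apply only when the field context designates that
space (a bare `513` is a gene id only inside a gene-id column).
Canonicalization is idempotent, and a string no rule matches raises
`UnknownDialect` — the row is quarantined with a logged warning and the build
continues; silent drops are never allowed.

## Rules and the forward chainer

Rules are data, not code: YAML files with a conjunctive body of triple
patterns, a Turtle-like head template, mint directives for fresh head
variables, and optional `mentions` provenance links from the matched record
to the generated class (every shipped BIO rule emits one, so record-level
provenance is uniform). The matcher performs an ordered nested join with
binding propagation; patterns whose predicate ends in `*` match the
reflexive-transitive closure (used for subclass guards; the subject must be
bound by an earlier pattern). Matching is deterministic — results are sorted
— so emission order never depends on store iteration order.

Batches run to fixpoint by naive re-evaluation with global duplicate
suppression: a head triple already in the graph counts as nothing new, and an
iteration adding zero triples terminates the batch (a configurable iteration
bound guards against non-termination; with monotone rules and deterministic
minting the fixpoint is reached in practice within two or three iterations).
Rules only add triples. Per-rule emission counts are logged because a rule
that suddenly produces zero triples is the cheapest possible detector of a
source-format change. Every emitted triple is tagged in a side derivation
index with (rule, binding, supporting records); the index is kept beside the
graph rather than reified into RDF so the published triple counts stay clean,
and it is written as a line-oriented sidecar keyed by triple hash.

## Identity resolution

Typing guards precede matching because mapping fields (dbXref-style) mix
semantic types. Compatibility means identical guard classes or one subsuming
the other through the loaded hierarchy (a gene-class guard is compatible with
a DNA-class guard); protein↔gene candidates are filtered, with counts logged
— and the same cross-type mapping records later drive the BIO-side
gene→protein link, so no information is lost by the filter. Closure uses a
hand-written union-find (union by size, path compression); singleton sets
*are* created for unmapped identifiers so every typed identifier yields a
denoted concept downstream. Set materialization emits exactly one
`kro:hasMember` triple per member and no type triple — the set's nature is
carried by its URI namespace — keeping a four-member set at four triples.
Each set then mints one BIO class (hash of the set URI), subClassOf the most
specific shared guard; a set whose members' guards are incompatible raises
`MixedTypeSet`, which signals an upstream filtering bug rather than a
representable state.

## BIO construction

All biomedical content is generated as fresh subclasses — no rule asserts on
an imported ontology class — which is what makes contradictory sources
tolerable: two conflicting annotations become two independent subclasses in
an open world, never an inconsistency. Aggregate sequence-abstraction classes
(gene-or-gene-product, gene-or-gene-product-or-variant) are encoded as plain
parallel superclasses rather than `owl:unionOf`, keeping everything emitted
inside the OWL-EL profile; drug–target assertions attach to the
…-or-variant aggregate because drug sources rarely say whether the drug binds
the gene, a product, or a variant. The gene→protein link uses a
placeholder relation `kro:indirectlyTemplates` (no standard relation PURL
fits "serves as the indirect template for" without also importing a full
transcription/translation event model, which is out of scope). Species links
(`obo:RO_0002162`) are derived from source-record taxon fields by rules, and
exist chiefly to power the disjoint-taxa quality check. Pathway records get a
coarse has-participant representation that coexists with the fine-grained
per-annotation classes over the same proteins — multiple granularities are
additive, never exclusive.

## Quality checks

Three detectors query for assertions that should not exist: (1) a BIO entity
linked to two taxa declared `owl:disjointWith` (only explicit axioms count;
sibling taxa without an axiom are not flagged, avoiding false positives);
(2) an identifier set containing ≥2 identifiers from one source namespace;
(3) an external identifier receiving exact-match links from ≥2 distinct
records of one source. A single planted cross-taxon mapping intrinsically
produces one finding of kinds (1), (2) *and* (3) — merging two
two-identifier proteins necessarily collides a namespace and reuses a target
— and the fixture manifest accounts for exactly that, which is why the
planted-error suite can demand precision = recall = 1.0.

## Synthetic data

The generator emulates the *shape* of real integration inputs, not their
content: a gene catalog with a mixed-type dbXref column, an id-mapping table
with deliberately varied lexical dialects, a 17-column GAF 2.x file, two
overlapping drug–target sources (so one interaction arrives from two
sources), a pathway table with multi-valued member cells, and a ~40-class
mini ontology (sequence types, a small process/component hierarchy, two
disjoint taxa, interaction/aboutness vocabulary; backbone terms reuse
genuine OBO PURLs, content is synthetic). Defaults: 18 genes across two taxa
(80% protein-coding, 75% with a second gene id, 2/3 of proteins with a second
protein id), 8 drugs (half with a second accession), 1–2 process annotations
and one component annotation per protein, 2 pathways, and an error plan of
one cross-taxon mapping, one many-to-one mapping, and two cross-type dbXref
entries. These sizes keep a full build under a second while exercising every
sharing, filtering and merging path at least twice; scaling the counts ×10
changes only runtimes, and a scaling test asserts the arithmetic holds.
Everything derives deterministically from the seed; the manifest (identity
partition, true annotations, planted errors and their expected findings, the
planted answer to the demo query) is computed from the construction plan
itself, never from pipeline output, so recovery tests are non-circular.

What the fixtures do **not** emulate: real accession schemes, XML dumps,
curation noise beyond the planted errors, skewed annotation distributions,
or anything at production scale. Passing tests therefore demonstrate the
correctness of the mechanisms (canonicalization, guarded matching, closure,
template arithmetic, provenance, planted-error recovery) — not performance or
recall on real databases, whose parsers are out of scope.

## Querying

The staged outputs are gzip N-Triples checkpoints; the graph lives in memory
(no triplestore deployment). The `query` subcommand accepts SPARQL 1.1, where
property paths (`rdfs:subClassOf*`) reach through transitive hierarchies. The
shipped case-study retrieval uses the package's own ordered matcher rather
than the generic SPARQL engine: on this workload the generic engine's join
order is catastrophic, while the ordered conjunctive form (anchor on the
mitochondrion restriction, then widen) runs in milliseconds; the pattern list
in `pipeline.py` documents the block structure (localization → aggregate →
process participation → interaction → drug identifier). Queries against
aggregates must first step down to a fresh subclass of the aggregate per
clause — reusing one variable across clauses would demand a single product
satisfying every condition simultaneously.

## Limitations

Desk scale throughout: naive rule re-evaluation (no semi-naive optimization),
in-memory graphs, no streaming ingestion, no XML source formats, no external
reasoner integration (EL classification would add entailments the property
paths cannot reach, e.g. subclass hierarchies nested under restrictions), no
homology abstraction layer, and no automated repair or blocking of assertions
the quality checks flag — findings are reported with evidence and left to a
curator.
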