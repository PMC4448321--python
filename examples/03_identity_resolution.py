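"""Identifier canonicalization, type-guarded matching, and set formation.

Lexical dialects of one gene identifier all canonicalize to a single ICE URI;
exact-match edges are closed with union-find into disjoint sets whose URIs are
permutation-invariant hashes of the sorted members.
"""

from icebio import DialectTable, FieldContext, mint_set_uri, union_find_closure
from icebio.identity import ExactMatchEdge

dialects = DialectTable.builtin()

print("canonicalization of NCBI-gene-style dialects:")
gene_field = FieldContext("genecat", "gene_id", "EG")
for raw in ["EG513", "EG:513", "EG_513", "513"]:
    print(f"  {raw!r:10} → {dialects.canonicalize(raw, gene_field)}")

print("\npermutation-invariant set URIs:")
a = mint_set_uri(["http://x.org/HGNC_837", "http://x.org/EG_513"])
b = mint_set_uri(["http://x.org/EG_513", "http://x.org/HGNC_837"])
print(f"  {{HGNC,EG}} → {a}")
print(f"  {{EG,HGNC}} → {b}  (identical: {a == b})")

print("\nunion-find closure of pairwise matches into disjoint sets:")
ids = [dialects.canonicalize(x) for x in ["EG:513", "HGNC:837", "PA700", "DB00001"]]
gene_ids, drug_ids = ids[:2], ids[2:]
edges = [
    ExactMatchEdge(gene_ids[0], gene_ids[1], gene_ids[0]),
    ExactMatchEdge(drug_ids[0], drug_ids[1], drug_ids[0]),
]
for idset in union_find_closure(edges, ids):
    members = [str(m).rsplit("/", 1)[-1] for m in idset.members]
    print(f"  {idset.uri.rsplit('/', 1)[-1]}: {members}")
# Two disjoint sets come out — one per biomedical concept — and each will
# yield exactly one BIO class that every member identifier denotes.
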