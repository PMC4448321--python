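"""BIO-side construction: the shipped rule batches and their accounting.

The biomedical half of the graph is generated entirely by declarative rule
batches (packaged under ``icebio/data/rules``): species links, the
sequence-abstraction aggregates and gene→product links, the five-triple
GO-annotation pattern, the nine-triple drug–gene interaction pattern, and the
coarse-grained pathway pattern. Every generated assertion introduces a fresh
hash-minted subclass — no rule asserts on an imported ontology class — so
contradictory source records coexist as independent subclasses. Restriction
URIs are pure functions of (property, filler), which makes the graph-wide
restriction-node count equal the number of distinct such pairs.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Set, Tuple

from rdflib import Graph, URIRef
from rdflib.namespace import OWL

from .rule_engine import DerivationIndex, RuleBatch, load_rule_batch, run_batch_to_fixpoint

#: Stage order of the shipped batches (file naming encodes the order).
BUILTIN_BATCHES = ("40_taxon.yaml", "50_abstractions.yaml", "60_goa.yaml", "70_interactions.yaml", "80_pathway.yaml")


def load_builtin_batch(filename: str) -> RuleBatch:
    ref = resources.files("icebio.data.rules").joinpath(filename)
    with resources.as_file(ref) as path:
        return load_rule_batch(Path(path))


def load_builtin_batches() -> List[RuleBatch]:
    return [load_builtin_batch(name) for name in BUILTIN_BATCHES]


def apply_taxon_rules(graph: Graph, derivations: Optional[DerivationIndex] = None) -> Dict[str, int]:
    return run_batch_to_fixpoint(load_builtin_batch("40_taxon.yaml"), graph, derivations)


def build_abstractions(graph: Graph, derivations: Optional[DerivationIndex] = None) -> Dict[str, int]:
    """Aggregate classes per gene plus gene→protein indirect-template links.

    A protein whose mapping record pairs it with no known gene is still
    represented (its BIO class exists from its identifier set); the orphan is
    simply absent from any aggregate, which the census below reports.
    """
    return run_batch_to_fixpoint(load_builtin_batch("50_abstractions.yaml"), graph, derivations)


def goa_rules(graph: Graph, derivations: Optional[DerivationIndex] = None) -> Dict[str, int]:
    return run_batch_to_fixpoint(load_builtin_batch("60_goa.yaml"), graph, derivations)


def interaction_rules(graph: Graph, derivations: Optional[DerivationIndex] = None) -> Dict[str, int]:
    return run_batch_to_fixpoint(load_builtin_batch("70_interactions.yaml"), graph, derivations)


def multi_granularity_rules(graph: Graph, derivations: Optional[DerivationIndex] = None) -> Dict[str, int]:
    return run_batch_to_fixpoint(load_builtin_batch("80_pathway.yaml"), graph, derivations)


def restriction_census(graph: Graph) -> Tuple[int, int]:
    """(restriction node count, distinct (onProperty, someValuesFrom) pairs).

    Restriction reuse makes these equal; a divergence flags broken minting.
    """
    from rdflib.namespace import RDF

    nodes: Set[URIRef] = set(graph.subjects(RDF.type, OWL.Restriction))
    pairs = set()
    for node in nodes:
        prop = next(graph.objects(node, OWL.onProperty), None)
        filler = next(graph.objects(node, OWL.someValuesFrom), None)
        pairs.add((prop, filler))
    return len(nodes), len(pairs)


def orphan_proteins(graph: Graph) -> List[URIRef]:
    """Protein BIO classes lacking a coding gene (warned, still represented)."""
    from .namespaces import INDIRECTLY_TEMPLATES, OBO
    from rdflib.namespace import RDFS

    proteins = {s for s in graph.subjects(RDFS.subClassOf, OBO.PR_000000001)}
    templated = set(graph.objects(None, INDIRECTLY_TEMPLATES))
    return sorted(proteins - templated)
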