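"""Forward chaining: matching vs a nested-loop oracle, instantiation, fixpoint."""

from __future__ import annotations

import itertools
import random

import pytest
from rdflib import Graph, URIRef
from rdflib.namespace import OWL, RDF, RDFS

from icebio.namespaces import DENOTES, DENOTES_SUBCLASS_OF, KIAO, OBO
from icebio.rule_engine import (
    MintDirective,
    NonTermination,
    Rule,
    RuleBatch,
    UnboundVariable,
    Var,
    expand_macro,
    expand_macro_assertion,
    instantiate,
    match,
    parse_term,
    run_batch_to_fixpoint,
)


def u(i):
    return URIRef(f"http://x.org/n{i}")


def random_graph(rng: random.Random, n_triples: int, n_nodes: int = 20, n_preds: int = 4) -> Graph:
    g = Graph()
    while len(g) < n_triples:
        g.add((u(rng.randrange(n_nodes)), u(100 + rng.randrange(n_preds)), u(rng.randrange(n_nodes))))
    return g


def random_body(rng: random.Random, n_patterns: int, n_nodes: int = 20, n_preds: int = 4):
    """Patterns mixing shared variables and constants."""
    vars_pool = [Var(x) for x in "abcdef"]
    body = []
    for _ in range(n_patterns):
        s = rng.choice(vars_pool) if rng.random() < 0.7 else u(rng.randrange(n_nodes))
        p = u(100 + rng.randrange(n_preds)) if rng.random() < 0.8 else rng.choice(vars_pool)
        o = rng.choice(vars_pool) if rng.random() < 0.7 else u(rng.randrange(n_nodes))
        body.append((s, p, o))
    return body


def nested_loop_join(body, graph):
    """Independent oracle: product over all triples, checked for consistency."""
    results = set()
    for combo in itertools.product(list(graph), repeat=len(body)):
        binding = {}
        ok = True
        for pattern, triple in zip(body, combo):
            for term, value in zip(pattern, triple):
                if isinstance(term, Var):
                    if binding.get(term.name, value) != value:
                        ok = False
                        break
                    binding[term.name] = value
                elif term != value:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            results.add(frozenset((k, str(v)) for k, v in binding.items()))
    return results


def test_single_pattern_counts():
    g = Graph()
    g.add((u(1), u(100), u(2)))
    g.add((u(3), u(100), u(4)))
    g.add((u(1), u(101), u(2)))
    bindings = match([(Var("s"), u(100), Var("o"))], g)
    assert len(bindings) == 2


def test_match_empty_graph():
    assert match([(Var("s"), u(100), Var("o"))], Graph()) == []


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
@pytest.mark.parametrize("n_patterns", [2, 3, 4])
def test_match_equals_nested_loop_oracle(seed, n_patterns):
    """Randomized graphs (small enough for the exponential oracle)."""
    rng = random.Random(seed * 10 + n_patterns)
    g = random_graph(rng, n_triples=18, n_nodes=8, n_preds=3)
    body = random_body(rng, n_patterns, n_nodes=8, n_preds=3)
    got = {frozenset((k, str(v)) for k, v in b.items()) for b in match(body, g)}
    assert got == nested_loop_join(body, g)


def test_match_oracle_on_larger_graphs_with_selective_bodies():
    """Up to 500 triples with 2-pattern bodies (oracle quadratic, still exact)."""
    rng = random.Random(99)
    g = random_graph(rng, n_triples=500, n_nodes=40, n_preds=5)
    body = [(Var("a"), u(101), Var("b")), (Var("b"), u(102), Var("c"))]
    got = {frozenset((k, str(v)) for k, v in b.items()) for b in match(body, g)}
    oracle = set()
    for s1, _, o1 in g.triples((None, u(101), None)):
        for s2, _, o2 in g.triples((None, u(102), None)):
            if o1 == s2:
                oracle.add(frozenset({("a", str(s1)), ("b", str(o1)), ("c", str(o2))}))
    assert got == oracle


def test_transitive_pattern_reflexive_closure():
    g = Graph()
    g.add((u(1), RDFS.subClassOf, u(2)))
    g.add((u(2), RDFS.subClassOf, u(3)))
    body = [(u(1), parse_term("rdfs:subClassOf*"), Var("o"))]
    objects = {str(b["o"]) for b in match(body, g)}
    assert objects == {str(u(1)), str(u(2)), str(u(3))}


GOA_HEAD = tuple(
    tuple(parse_term(t) for t in pat)
    for pat in [
        ["?newProcess", "rdfs:subClassOf", "?goProcess"],
        ["?participant", "rdf:type", "owl:Restriction"],
        ["?participant", "owl:onProperty", "obo:RO_0000057"],
        ["?participant", "owl:someValuesFrom", "?protein"],
        ["?newProcess", "rdfs:subClassOf", "?participant"],
    ]
)
GOA_MINT = {
    "participant": MintDirective("restriction", ("obo:RO_0000057", "?protein")),
    "newProcess": MintDirective("bio-class", ("goa", "?goProcess", "?protein"), uri_prefix="P_"),
}


def test_instantiate_goa_template_five_triples():
    binding = {"protein": u(1), "goProcess": OBO.GO_0006119}
    triples, full = instantiate(GOA_HEAD, binding, GOA_MINT)
    assert len(triples) == 5
    restriction = full["participant"]
    assert (restriction, RDF.type, OWL.Restriction) in triples
    assert (restriction, OWL.someValuesFrom, u(1)) in triples
    assert (full["newProcess"], RDFS.subClassOf, OBO.GO_0006119) in triples


def test_instantiate_is_deterministic():
    binding = {"protein": u(1), "goProcess": OBO.GO_0006119}
    assert instantiate(GOA_HEAD, binding, GOA_MINT)[0] == instantiate(GOA_HEAD, binding, GOA_MINT)[0]


def test_unbound_head_variable_rejected():
    with pytest.raises(UnboundVariable):
        instantiate(GOA_HEAD, {"protein": u(1)}, {})  # goProcess unbound, no mint
    with pytest.raises(UnboundVariable):
        Rule("r", body=((Var("x"), u(1), Var("y")),), head=((Var("z"), u(1), Var("y")),))


def chain_batch():
    """Rule B consumes rule A's output."""
    a = Rule(
        "a",
        body=((Var("x"), u(100), Var("y")),),
        head=((Var("x"), u(101), Var("y")),),
    )
    b = Rule(
        "b",
        body=((Var("x"), u(101), Var("y")), (Var("y"), u(101), Var("z"))),
        head=((Var("x"), u(102), Var("z")),),
    )
    return RuleBatch("chain", (a, b))


def test_fixpoint_idempotence():
    g = Graph()
    for i in range(4):
        g.add((u(i), u(100), u(i + 1)))
    batch = chain_batch()
    run_batch_to_fixpoint(batch, g)
    size = len(g)
    counts = run_batch_to_fixpoint(batch, g)
    assert len(g) == size
    assert all(n == 0 for n in counts.values())


def test_chained_rules_equal_saturation_oracle():
    """Brute-force saturation: apply both rules' semantics until no change."""
    g = Graph()
    edges = [(0, 1), (1, 2), (2, 3), (0, 2)]
    for s, o in edges:
        g.add((u(s), u(100), u(o)))
    run_batch_to_fixpoint(chain_batch(), g)

    # oracle over plain python sets
    p101 = set(edges)
    p102 = set()
    changed = True
    while changed:
        before = (len(p101), len(p102))
        p102 |= {(x, z) for (x, y1) in p101 for (y2, z) in p101 if y1 == y2}
        changed = (len(p101), len(p102)) != before
    got_102 = {(s, o) for s, _, o in g.triples((None, u(102), None))}
    assert got_102 == {(u(s), u(o)) for s, o in p102}


def test_nontermination_guard():
    g = Graph()
    g.add((u(1), u(100), u(2)))
    batch = chain_batch()
    with pytest.raises(NonTermination):
        run_batch_to_fixpoint(batch, g, max_iterations=0)


def test_zero_emission_rule_is_reported():
    g = Graph()
    g.add((u(1), u(100), u(2)))
    dead = Rule("dead", body=((Var("x"), u(999), Var("y")),), head=((Var("x"), u(102), Var("y")),))
    counts = run_batch_to_fixpoint(RuleBatch("b", (dead,)), g)
    assert counts["dead"] == 0


class TestMacroExpansion:
    def test_one_assertion_two_triples(self):
        x, z = URIRef(f"{KIAO}EG_513_ICE"), OBO.SO_0000352
        triples = expand_macro_assertion(x, z)
        assert len(triples) == 2
        assert triples[0][1] == DENOTES
        assert triples[1][1] == RDFS.subClassOf
        assert triples[0][2] == triples[1][0]  # shared intermediate Y

    def test_expansion_is_stable(self):
        x, z = URIRef(f"{KIAO}EG_513_ICE"), OBO.SO_0000352
        assert expand_macro_assertion(x, z) == expand_macro_assertion(x, z)

    def test_n_assertions_2n_triples_n_intermediates(self):
        g = Graph()
        n = 9
        for i in range(n):
            g.add((URIRef(f"{KIAO}EG_{i}_ICE"), DENOTES_SUBCLASS_OF, OBO.SO_0000352))
        triples = expand_macro(g)
        assert len(triples) == 2 * n
        assert len({t[2] for t in triples if t[1] == DENOTES}) == n


def test_mint_directives_may_reference_each_other():
    rule_mint = {
        "inner": MintDirective("bio-class", ("tag1", "?x")),
        "outer": MintDirective("restriction", ("obo:RO_0000057", "?inner")),
    }
    head = ((Var("outer"), RDF.type, OWL.Restriction),)
    triples, full = instantiate(head, {"x": u(1)}, rule_mint)
    assert full["outer"] == instantiate(head, {"x": u(1)}, rule_mint)[1]["outer"]


def test_monotonicity_rules_never_delete():
    g = Graph()
    g.add((u(0), u(100), u(1)))
    before = set(g)
    run_batch_to_fixpoint(chain_batch(), g)
    assert before <= set(g)
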