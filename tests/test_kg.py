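"""Knowledge-graph pipeline: family filtering, self-loops, restart walks,
pathway-anchored extraction, and consistency filtering."""

import networkx as nx
import numpy as np
import pytest

from pathddi import kg as kgmod
from pathddi.io import DDITable, DrugTable
from pathddi.synthetic import SyntheticSpec, gen_kg


def kg_from(*triples):
    return kgmod.HeteroKG.from_triples(triples)


def chain_kg(n_genes: int):
    """Drug - g1 - ... - gn - Pathway chain."""
    nodes = (["Compound::d"] + [f"Gene::g{i}" for i in range(n_genes)]
             + ["Pathway::p"])
    triples = [(a, "r", b) for a, b in zip(nodes, nodes[1:])]
    return kg_from(*triples)


def test_entity_family_prefixes():
    assert kgmod.entity_family("Compound::DB01") == "Compound"
    assert kgmod.entity_family("Side-effect::S1") == "SideEffect"
    assert kgmod.entity_family("Atc::A01") == "Other"


def test_filter_families_variants():
    kg = kg_from(
        ("Compound::c", "t", "Gene::g"),
        ("Compound::c", "causes", "Side-effect::s"),
        ("Gene::g", "x", "Atc::other"),
    )
    cgpds = kgmod.filter_families(kg, "CGPDS")
    assert ("Compound::c", "t", "Gene::g") in cgpds.triples()
    assert ("Compound::c", "causes", "Side-effect::s") in cgpds.triples()
    assert all("Atc" not in h and "Atc" not in t
               for h, _, t in cgpds.triples())
    cgpd = kgmod.filter_families(kg, "CGPD")
    assert all("Side-effect" not in t for _, _, t in cgpd.triples())
    with pytest.raises(ValueError):
        kgmod.filter_families(kg, "CG")


def test_filter_monotonicity_on_synthetic_kg(tiny_spec):
    kg, _ = gen_kg(tiny_spec)
    cgpds = kgmod.filter_families(kg, "CGPDS")
    cgpd = kgmod.filter_families(kg, "CGPD")
    assert cgpd.n_nodes <= cgpds.n_nodes
    assert cgpd.n_edges <= cgpds.n_edges


def test_attach_self_loops():
    kg = kg_from(("Compound::a", "t", "Gene::g"))
    kg.add_node("Compound::lonely")
    kgmod.attach_self_loops(kg, ["Compound::a", "Compound::lonely"])
    assert kg.graph.degree("Compound::a") == 1          # unchanged
    # self-loops count degree 2 in networkx; the loop edge exists
    assert kg.graph.has_edge("Compound::lonely", "Compound::lonely")
    before = kg.n_edges
    kgmod.attach_self_loops(kg, [])
    assert kg.n_edges == before


def test_random_walk_degenerate_cases():
    kg = kg_from(("Compound::a", "t", "Gene::g"), ("Gene::g", "m", "Pathway::p"))
    kg.add_node("Compound::lonely")
    kgmod.attach_self_loops(kg, ["Compound::lonely"])
    visited, induced = kgmod.random_walk_neighborhood(
        kg, "Compound::lonely", steps=10, restart_prob=0.3, iterations=5,
        spread=100, rng_seed=0)
    assert visited == {"Compound::lonely"}
    assert induced.n_edges == 1                         # the self-loop
    # restart probability 1 never leaves the seed
    visited, _ = kgmod.random_walk_neighborhood(
        kg, "Compound::a", steps=10, restart_prob=1.0, iterations=5,
        spread=100, rng_seed=0)
    assert visited == {"Compound::a"}
    with pytest.raises(KeyError):
        kgmod.random_walk_neighborhood(kg, "Compound::absent", 1, 0.3, 1, 10, 0)


def test_random_walk_reaches_component_with_generous_budget():
    kg = kg_from(("Pathway::p", "r", "Gene::g"), ("Gene::g", "r", "Compound::c"))
    visited, induced = kgmod.random_walk_neighborhood(
        kg, "Compound::c", steps=50, restart_prob=0.3, iterations=50,
        spread=10_000, rng_seed=1)
    assert visited == {"Pathway::p", "Gene::g", "Compound::c"}
    assert induced.n_edges == 2


def test_random_walk_determinism():
    kg, _ = gen_kg(SyntheticSpec(n_drugs=8, n_pairs=10, seed=2))
    args = dict(steps=40, restart_prob=0.3, iterations=20, spread=50,
                rng_seed=5)
    v1, g1 = kgmod.random_walk_neighborhood(kg, "Compound::D0000", **args)
    v2, g2 = kgmod.random_walk_neighborhood(kg, "Compound::D0000", **args)
    assert v1 == v2
    assert sorted(g1.triples()) == sorted(g2.triples())


def test_four_hop_chain_is_retained_five_hop_flagged():
    four = chain_kg(3)   # drug -g-g-g- pathway: distance 4
    sub = kgmod.pathway_anchored_extract("Compound::d", four, hop_limit=4)
    assert not sub.unreachable
    assert "Compound::d" in sub.entities
    assert kgmod.verify_hop_guarantee(sub, hop_limit=4)

    five = chain_kg(4)   # distance 5: beyond the hop limit
    sub5 = kgmod.pathway_anchored_extract("Compound::d", five, hop_limit=4)
    assert sub5.unreachable


def test_star_extraction_keeps_all_leaves():
    triples = [("Pathway::hub", "r", f"Gene::g{i}") for i in range(6)]
    kg = kg_from(*triples)
    sub = kgmod.pathway_anchored_extract("Gene::g0", kg)
    assert len(sub.entities) == 7
    assert sub.anchor_pathways == {"Pathway::hub"}


def test_extract_without_pathway_is_flagged_not_raised():
    kg = kg_from(("Compound::d", "t", "Gene::g"))
    sub = kgmod.pathway_anchored_extract("Compound::d", kg)
    assert sub.unreachable


def test_consistency_filter_set_arithmetic():
    drugs = DrugTable([(f"d{i}", "CC") for i in range(5)])
    ddi = DDITable([("d0", "d1", 1), ("d1", "d2", 2),
                    ("d0", "d4", 1), ("d2", "d3", 0)])
    subgraphs = {}
    for i in range(5):
        sub = kgmod.DrugSubgraph(drug=f"d{i}",
                                 edges=[(f"d{i}", "t", "Gene::g")],
                                 entities={f"d{i}", "Gene::g"})
        if i == 4:
            sub.unreachable = True
        subgraphs[f"d{i}"] = sub
    drugs_f, ddi_f, report = kgmod.consistency_filter(drugs, ddi, subgraphs)
    assert len(drugs_f) == 4
    assert len(ddi_f) == 3                      # the d0-d4 row is dropped
    assert report == [("d4", "pathway-unreachable")]

    # identity when nothing is removed
    subgraphs["d4"].unreachable = False
    drugs_f, ddi_f, report = kgmod.consistency_filter(drugs, ddi, subgraphs)
    assert len(drugs_f) == 5 and len(ddi_f) == 4 and report == []


def test_consistency_filter_no_usable_edges():
    drugs = DrugTable([("d0", "CC")])
    ddi = DDITable([])
    sub = kgmod.DrugSubgraph(drug="d0", entities={"d0"},
                             edges=[("d0", kgmod.SELF_RELATION, "d0")])
    _, _, report = kgmod.consistency_filter(drugs, ddi, {"d0": sub})
    assert report == [("d0", "no-usable-edges")]


def test_stage_counts():
    kg = kg_from(("a::x", "r", "b::y"), ("b::y", "r", "c::z"),
                 ("c::z", "r", "a::x"))
    assert kgmod.stage_counts(kg) == (3, 3)
    assert kgmod.stage_counts(kgmod.HeteroKG()) == (0, 0)


def test_hop_guarantee_bfs_on_synthetic_pipeline(tiny_spec, tiny_cfg):
    kg, _ = gen_kg(tiny_spec)
    kg = kgmod.filter_families(kg, "CGPDS")
    drugs = [f"Compound::D{i:04d}" for i in range(tiny_spec.n_drugs)]
    kgmod.attach_self_loops(kg, drugs)
    for i, drug in enumerate(drugs):
        _, nb = kgmod.random_walk_neighborhood(
            kg, drug, tiny_cfg.walk_steps, tiny_cfg.walk_restart_prob,
            tiny_cfg.walk_iterations, tiny_cfg.walk_spread, rng_seed=i)
        sub = kgmod.pathway_anchored_extract(drug, nb, hop_limit=4)
        if not sub.unreachable:
            # independent BFS verification
            g = sub.to_graph()
            dist = nx.single_source_shortest_path_length(g, drug)
            assert min(dist.get(p, np.inf)
                       for p in sub.anchor_pathways) <= 4


def test_budget_halving_never_reduces_unreachable_count(tiny_spec):
    kg, _ = gen_kg(tiny_spec)
    kg = kgmod.filter_families(kg, "CGPDS")
    drugs = [f"Compound::D{i:04d}" for i in range(tiny_spec.n_drugs)]
    kgmod.attach_self_loops(kg, drugs)

    def unreachable_count(steps, iterations):
        n = 0
        for i, drug in enumerate(drugs):
            _, nb = kgmod.random_walk_neighborhood(
                kg, drug, steps, 0.3, iterations, spread=500, rng_seed=i)
            if kgmod.pathway_anchored_extract(drug, nb).unreachable:
                n += 1
        return n

    full = unreachable_count(8, 4)
    halved = unreachable_count(4, 4)
    assert halved >= full


def test_subgraph_json_roundtrip():
    sub = kgmod.DrugSubgraph(
        drug="Compound::d", entities={"Compound::d", "Gene::g", "Pathway::p"},
        relations={"t", "m"}, anchor_pathways={"Pathway::p"},
        edges=[("Compound::d", "t", "Gene::g"), ("Gene::g", "m", "Pathway::p")],
        families={"Compound::d": "Compound", "Gene::g": "Gene",
                  "Pathway::p": "Pathway"})
    back = kgmod.DrugSubgraph.from_json(sub.to_json())
    assert back.entities == sub.entities
    assert back.relations == sub.relations
    assert sorted(back.edges) == sorted(sub.edges)
    assert back.S == sub.S == 5
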