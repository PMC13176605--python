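"""Interpretability: merged subgraphs, centrality correctness against
brute-force oracles, effect sizes, the screening pipeline, and distribution
summaries."""

import itertools

import networkx as nx
import numpy as np
import pytest

from pathddi import interpret as itp
from pathddi.io import DDITable
from pathddi.kg import DrugSubgraph
from pathddi.synthetic import gen_screen_case


# -- brute-force centrality oracles ------------------------------------------


def brute_centralities(G: nx.Graph):
    nodes = list(G.nodes)
    n = len(nodes)
    degree = {v: G.degree(v) / (n - 1) for v in nodes}

    # betweenness via explicit shortest-path enumeration
    betweenness = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        paths = list(nx.all_shortest_paths(G, s, t))
        for v in nodes:
            if v in (s, t):
                continue
            frac = sum(v in p for p in paths) / len(paths)
            betweenness[v] += frac
    norm = (n - 1) * (n - 2) / 2.0
    if norm > 0:
        betweenness = {v: b / norm for v, b in betweenness.items()}

    closeness = {
        v: (n - 1) / sum(nx.single_source_shortest_path_length(G, v).values())
        if n > 1 else 0.0
        for v in nodes
    }

    A = nx.to_numpy_array(G, nodelist=nodes)
    vals, vecs = np.linalg.eigh(A)
    principal = np.abs(vecs[:, np.argmax(vals)])
    principal /= np.linalg.norm(principal)
    eigenvector = dict(zip(nodes, principal))
    return degree, betweenness, closeness, eigenvector


def test_centralities_match_brute_force_on_all_small_graphs():
    """All connected graphs on 2..6 nodes (graph atlas, up to isomorphism)."""
    from networkx.generators.atlas import graph_atlas_g

    graphs = [G for G in graph_atlas_g()
              if 2 <= len(G) <= 6 and nx.is_connected(G)]
    assert len(graphs) > 100
    for G in graphs:
        result = itp.centralities(G)
        deg, bet, clo, eig = brute_centralities(G)
        for v in G.nodes:
            assert result[v]["degree"] == pytest.approx(deg[v], abs=1e-9)
            assert result[v]["betweenness"] == pytest.approx(bet[v], abs=1e-9)
            assert result[v]["closeness"] == pytest.approx(clo[v], abs=1e-9)
            assert result[v]["eigenvector"] == pytest.approx(eig[v], abs=1e-5)


def test_centrality_examples():
    path = nx.path_graph(["a", "b", "c"])
    c = itp.centralities(path)
    assert c["b"]["betweenness"] == pytest.approx(1.0)
    assert c["a"]["betweenness"] == 0.0
    star = nx.star_graph(5)
    assert itp.centralities(star)[0]["degree"] == pytest.approx(1.0)
    cycle = itp.centralities(nx.cycle_graph(6))
    for measure in itp.CENTRALITY_ORDER:
        values = {round(cycle[v][measure], 9) for v in range(6)}
        assert len(values) == 1
    with pytest.raises(ValueError):
        itp.centralities(nx.Graph())


# -- merged subgraphs ---------------------------------------------------------


def subgraph(drug, edges):
    nodes = {drug} | {x for e in edges for x in e}
    return DrugSubgraph(
        drug=drug, entities=nodes, relations={"r"},
        anchor_pathways={x for x in nodes if x.startswith("Pathway")},
        edges=[(u, "r", v) for u, v in edges],
        families={x: x.split("::")[0] for x in nodes},
    )


def test_merge_disjoint_subgraphs_has_no_connection():
    a = subgraph("Compound::a", [("Compound::a", "Pathway::p1")])
    b = subgraph("Compound::b", [("Compound::b", "Pathway::p2")])
    merged = itp.merge_subgraphs(a, b)
    assert merged.shared_pathways == set()
    assert not merged.connected_via_pathway


def test_merge_shared_pathway_sets_flag():
    a = subgraph("Compound::a", [("Compound::a", "Pathway::p")])
    b = subgraph("Compound::b", [("Compound::b", "Pathway::p")])
    merged = itp.merge_subgraphs(a, b)
    assert merged.shared_pathways == {"Pathway::p"}
    assert merged.connected_via_pathway
    assert merged.node_origin["Pathway::p"] == "shared"
    assert merged.node_origin["Compound::a"] == "a"


def test_merge_with_itself_marks_everything_shared():
    a = subgraph("Compound::a", [("Compound::a", "Gene::g"),
                                 ("Gene::g", "Pathway::p")])
    merged = itp.merge_subgraphs(a, a)
    assert set(merged.graph.nodes) == a.entities
    assert all(o == "shared" for o in merged.node_origin.values())


# -- effect sizes and weighting ----------------------------------------------


def test_cliffs_delta_complete_separation_and_ties():
    assert itp.cliffs_delta([3, 4, 5], [0, 1, 2]) == 1.0
    assert itp.cliffs_delta([0, 1, 2], [3, 4, 5]) == -1.0
    assert itp.cliffs_delta([1, 1], [1, 1]) == 0.0


def test_weighted_separation_rep_w():
    assert itp.weighted_separation([1, 1, 1, 1]) == pytest.approx(1.0)
    assert itp.weighted_separation([1, 0, 0, 0]) == pytest.approx(0.40)
    assert itp.weighted_separation([0, 1, 0, 0]) == pytest.approx(0.30)
    assert itp.weighted_separation([0, 0, 1, 0]) == pytest.approx(0.20)
    assert itp.weighted_separation([0, 0, 0, 1]) == pytest.approx(0.10)
    assert itp.weighted_separation([0, 0, 0, 0]) == 0.0
    assert itp.weighted_separation([1, 1, 1, 1], coverage=0.5) == pytest.approx(0.5)


def test_smd_degenerate_spread_is_capped():
    assert itp.standardized_mean_difference(np.ones(3), np.ones(3)) == 0.0
    assert itp.standardized_mean_difference(
        np.full(3, 2.0), np.ones(3)) == itp._SMD_CAP


# -- screening ----------------------------------------------------------------


def make_samples(pathway, interacting, noninteracting, n_partners=None):
    rec = itp.PathwaySamples(pathway=pathway,
                             n_interacting_partners=n_partners
                             or len(interacting))
    for v in interacting:
        rec.interacting.append({c: v for c in itp.CENTRALITY_ORDER})
    for v in noninteracting:
        rec.noninteracting.append({c: v for c in itp.CENTRALITY_ORDER})
    return rec


def test_bh_with_single_hypothesis_keeps_p():
    samples = {"Pathway::p": make_samples(
        "Pathway::p", [0.9, 0.8, 0.85, 0.95], [0.1, 0.2, 0.15, 0.05])}
    records = itp.screen_pathways("a", samples)
    stats = records[0].stats
    # four centralities with identical samples give identical p-values; BH
    # over m equal p-values returns q = p
    for c in itp.CENTRALITY_ORDER:
        assert stats[c].q == pytest.approx(stats[c].p)
        assert stats[c].q >= stats[c].p - 1e-12
        assert stats[c].delta == 1.0


def test_screen_passes_planted_and_rejects_flat():
    flat = make_samples("Pathway::null", [0.5] * 6, [0.5] * 6)
    planted = make_samples("Pathway::planted",
                           [0.8, 0.82, 0.85, 0.9, 0.87, 0.84],
                           [0.2, 0.25, 0.22, 0.3, 0.21, 0.26])
    records = itp.screen_pathways(
        "a", {"Pathway::null": flat, "Pathway::planted": planted})
    assert records[0].pathway == "Pathway::planted"
    assert records[0].passed
    null_rec = [r for r in records if r.pathway == "Pathway::null"][0]
    assert not null_rec.passed
    assert "no-significant-centrality" in null_rec.fail_reasons


def test_screen_coverage_filter_and_small_groups():
    low_cov = make_samples("Pathway::rare", [0.9, 0.8], [0.1, 0.2],
                           n_partners=10)
    records = itp.screen_pathways("a", {"Pathway::rare": low_cov},
                                  coverage_min=0.3)
    assert not records[0].passed
    assert "coverage" in records[0].fail_reasons

    tiny = make_samples("Pathway::tiny", [0.9], [0.1, 0.2])
    rec = itp.screen_pathways("a", {"Pathway::tiny": tiny})[0]
    assert all(rec.stats[c].skipped == "group-too-small"
               for c in itp.CENTRALITY_ORDER)


def test_screen_tie_break_is_lexicographic():
    x, y = [0.8, 0.9, 0.85, 0.88, 0.92, 0.86], [0.1, 0.2, 0.15, 0.12, 0.18, 0.16]
    samples = {"Pathway::b": make_samples("Pathway::b", x, y),
               "Pathway::a": make_samples("Pathway::a", x, y)}
    records = itp.screen_pathways("anchor", samples)
    assert [r.pathway for r in records] == ["Pathway::a", "Pathway::b"]


def test_planted_screen_case_end_to_end():
    subgraphs, ddi, anchor, planted = gen_screen_case(rng_seed=0)
    _, _, samples = itp.partner_group_distributions(anchor, 1, ddi, subgraphs)
    records = itp.screen_pathways(anchor, samples)
    assert records[0].pathway == planted
    assert records[0].passed


def test_partner_groups_require_both_sides():
    subgraphs, ddi, anchor, _ = gen_screen_case(rng_seed=1)
    with pytest.raises(ValueError):
        itp.partner_group_distributions(anchor, 0, ddi, subgraphs)
    with pytest.raises(ValueError):
        itp.partner_group_distributions(anchor, 99, ddi, subgraphs)


# -- distribution summaries ---------------------------------------------------


def test_percentile_marker_on_1_to_100():
    summary = itp.distribution_summary(np.arange(1.0, 51.0),
                                       np.arange(51.0, 101.0))
    assert 95.0 <= summary.percentile_95 <= 96.0
    assert (summary.rug_points > summary.percentile_95).all()


def test_identical_groups_have_zero_mean_difference():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    summary = itp.distribution_summary(x, x.copy())
    assert summary.mean_difference == 0.0
    np.testing.assert_allclose(summary.density_interacting,
                               summary.density_noninteracting)


def test_degenerate_and_minimal_summaries():
    const = itp.distribution_summary(np.ones(5), np.ones(4))
    assert const.degenerate
    two = itp.distribution_summary(np.array([1.0, 2.0]), np.array([3.0, 4.0]))
    assert not two.degenerate
    with pytest.raises(ValueError):
        itp.distribution_summary(np.array([1.0]), np.array([1.0, 2.0]))


def test_plot_writes_file(tmp_path):
    summary = itp.distribution_summary(np.arange(10.0), np.arange(5.0, 15.0))
    out = tmp_path / "kde.png"
    itp.plot_distribution_summary(summary, out, title="demo")
    assert out.exists() and out.stat().st_size > 0
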