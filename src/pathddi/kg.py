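"""Heterogeneous knowledge-graph pipeline.

Stages, in pipeline order:

1. family filtering — keep only entities from the biologically relevant
   families (Compound, Gene, Pathway, Disease, and optionally Side-effect);
   an edge survives only if both endpoints do;
2. self-loop attachment for drugs left without incident edges, so walks do
   not degenerate;
3. random walk with restart from each drug to sample its neighborhood
   (independent walks with a per-transition restart probability and a cap
   on the number of distinct visited nodes);
4. pathway-anchored extraction — within the sampled neighborhood, keep only
   nodes whose undirected shortest-path distance to the nearest pathway node
   is at most the hop limit (default 4);
5. consistency filtering — drop drugs whose subgraphs have no usable edges or
   no reachable pathway, together with every interaction row touching them.

The graph is treated as an undirected multigraph throughout: reachability
between drugs and pathways is the quantity of interest and relation
directions in heterogeneous biomedical graphs are not consistent.  Hop
counting uses the simple-graph projection of the multigraph.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

FAMILIES = ("Compound", "Gene", "Pathway", "Disease", "SideEffect", "Other")
VARIANT_FAMILIES = {
    "CGPDS": {"Compound", "Gene", "Pathway", "Disease", "SideEffect"},
    "CGPD": {"Compound", "Gene", "Pathway", "Disease"},
}
_DEFAULT_PREFIX_MAP = {
    "Compound": "Compound",
    "Gene": "Gene",
    "Pathway": "Pathway",
    "Disease": "Disease",
    "Side-effect": "SideEffect",
    "SideEffect": "SideEffect",
}
SELF_RELATION = "self"


def entity_family(entity_id: str, prefix_map: dict[str, str] | None = None) -> str:
    """Family of a typed identifier; the ``Family::name`` prefix convention
    is the default, with a configurable prefix map for other dialects."""
    prefix_map = prefix_map or _DEFAULT_PREFIX_MAP
    prefix = entity_id.split("::", 1)[0]
    return prefix_map.get(prefix, "Other")


class HeteroKG:
    """Typed multigraph of entities and relations."""

    def __init__(self):
        self.graph = nx.MultiGraph()

    # -- construction ---------------------------------------------------------

    @classmethod
    def from_triples(cls, triples, prefix_map: dict[str, str] | None = None
                     ) -> "HeteroKG":
        kg = cls()
        for head, rel, tail in triples:
            kg.add_triple(head, rel, tail, prefix_map=prefix_map)
        return kg

    def add_node(self, entity_id: str, family: str | None = None,
                 prefix_map: dict[str, str] | None = None) -> None:
        if family is None:
            family = entity_family(entity_id, prefix_map)
        self.graph.add_node(entity_id, family=family)

    def add_triple(self, head: str, rel: str, tail: str,
                   prefix_map: dict[str, str] | None = None) -> None:
        self.add_node(head, prefix_map=prefix_map)
        self.add_node(tail, prefix_map=prefix_map)
        self.graph.add_edge(head, tail, relation=rel)

    # -- queries --------------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def family_of(self, node: str) -> str:
        return self.graph.nodes[node]["family"]

    def nodes_of_family(self, family: str) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True)
                if d["family"] == family}

    def triples(self) -> list[tuple[str, str, str]]:
        return [(h, d["relation"], t)
                for h, t, d in self.graph.edges(data=True)]

    def __contains__(self, node: str) -> bool:
        return node in self.graph


def stage_counts(obj) -> tuple[int, int]:
    """(node count, edge count) of a KG or drug subgraph, for audit logs."""
    if isinstance(obj, HeteroKG):
        return obj.n_nodes, obj.n_edges
    if isinstance(obj, DrugSubgraph):
        return len(obj.entities), len(obj.edges)
    if isinstance(obj, nx.Graph):
        return obj.number_of_nodes(), obj.number_of_edges()
    raise TypeError(f"cannot count stages of {type(obj).__name__}")


def filter_families(kg: HeteroKG, variant: str) -> HeteroKG:
    """Keep nodes of the variant's entity families; keep an edge only if both
    endpoints survive.  Surviving nodes are retained even if isolated."""
    if variant not in VARIANT_FAMILIES:
        raise ValueError(f"unknown dataset variant {variant!r}")
    keep = VARIANT_FAMILIES[variant]
    out = HeteroKG()
    for node, data in kg.graph.nodes(data=True):
        if data["family"] in keep:
            out.add_node(node, family=data["family"])
    for h, t, data in kg.graph.edges(data=True):
        if h in out.graph and t in out.graph:
            out.graph.add_edge(h, t, relation=data["relation"])
    return out


def attach_self_loops(kg: HeteroKG, drugs) -> HeteroKG:
    """Give every listed drug with zero incident edges one self-loop so random
    walks seeded there do not degenerate.  Returns the same KG, mutated."""
    for drug in drugs:
        if drug not in kg.graph:
            kg.add_node(drug, family="Compound")
        if kg.graph.degree(drug) == 0:
            kg.graph.add_edge(drug, drug, relation=SELF_RELATION)
    return kg


def random_walk_neighborhood(kg: HeteroKG, seed_drug: str, steps: int,
                             restart_prob: float, iterations: int,
                             spread: int, rng_seed: int
                             ) -> tuple[set[str], HeteroKG]:
    """Random walk with restart from ``seed_drug``.

    Runs ``iterations`` independent walks of at most ``steps`` transitions; at
    each transition the walker returns to the seed with probability
    ``restart_prob``, otherwise moves along a uniformly chosen incident edge
    (parallel edges count with multiplicity).  Distinct visited nodes
    accumulate until ``spread`` is reached.  Returns the visited set and the
    subgraph induced on it.
    """
    if seed_drug not in kg.graph:
        raise KeyError(f"seed drug {seed_drug!r} not in knowledge graph")
    rng = np.random.default_rng(rng_seed)
    component = nx.node_connected_component(kg.graph, seed_drug)
    budget = min(spread, len(component))  # walks cannot leave the component

    nbrs: dict[str, list[str]] = {}

    def neighbors(node: str) -> list[str]:
        if node not in nbrs:
            nbrs[node] = [t for _, t in kg.graph.edges(node)]
        return nbrs[node]

    visited = {seed_drug}
    done = False
    for _ in range(iterations):
        current = seed_drug
        restarts = rng.random(steps) < restart_prob
        for step in range(steps):
            if restarts[step]:
                current = seed_drug
                continue
            out = neighbors(current)
            if not out:
                break
            current = out[rng.integers(len(out))]
            if current not in visited:
                visited.add(current)
                if len(visited) >= budget:
                    done = True
                    break
        if done:
            break

    induced = HeteroKG()
    for node in visited:
        induced.add_node(node, family=kg.family_of(node))
    for h, t, data in kg.graph.edges(data=True):
        if h in visited and t in visited:
            induced.graph.add_edge(h, t, relation=data["relation"])
    return visited, induced


@dataclass
class DrugSubgraph:
    """Pathway-anchored entity/relation inventory of one drug.

    ``entities`` and ``relations`` feed the stacked embedding matrix; the
    size symbol is ``S = |entities| + |relations|``.  ``unreachable`` flags
    drugs whose neighborhood holds no pathway within the hop limit.
    """

    drug: str
    entities: set[str] = field(default_factory=set)
    relations: set[str] = field(default_factory=set)
    anchor_pathways: set[str] = field(default_factory=set)
    edges: list[tuple[str, str, str]] = field(default_factory=list)
    families: dict[str, str] = field(default_factory=dict)
    unreachable: bool = False

    @property
    def S(self) -> int:
        return len(self.entities) + len(self.relations)

    def has_usable_edges(self) -> bool:
        return any(rel != SELF_RELATION for _, rel, _ in self.edges)

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        for node in self.entities:
            g.add_node(node, family=self.families.get(node, "Other"))
        for h, rel, t in self.edges:
            g.add_edge(h, t, relation=rel)
        return g

    # -- JSON serialization ----------------------------------------------------

    def to_json(self) -> str:
        return json.dumps({
            "drug": self.drug,
            "unreachable": self.unreachable,
            "anchor_pathways": sorted(self.anchor_pathways),
            "nodes": [{"id": n, "family": self.families.get(n, "Other")}
                      for n in sorted(self.entities)],
            "relations": sorted(self.relations),
            "edges": [list(e) for e in sorted(self.edges)],
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "DrugSubgraph":
        d = json.loads(text)
        return cls(
            drug=d["drug"],
            entities={n["id"] for n in d["nodes"]},
            relations=set(d["relations"]),
            anchor_pathways=set(d["anchor_pathways"]),
            edges=[tuple(e) for e in d["edges"]],
            families={n["id"]: n["family"] for n in d["nodes"]},
            unreachable=d["unreachable"],
        )


def pathway_anchored_extract(drug: str, neighborhood: HeteroKG,
                             hop_limit: int = 4) -> DrugSubgraph:
    """Keep neighborhood nodes within ``hop_limit`` undirected hops of the
    nearest pathway node.  A neighborhood without a pathway, or whose drug
    falls outside every pathway's hop ball, is flagged unreachable."""
    anchors = neighborhood.nodes_of_family("Pathway")
    sub = DrugSubgraph(drug=drug)
    if not anchors:
        sub.unreachable = True
        sub.entities = {drug}
        sub.families = {drug: neighborhood.family_of(drug)
                        if drug in neighborhood else "Compound"}
        return sub

    simple = nx.Graph(neighborhood.graph)  # hop counting on simple projection
    dist = nx.multi_source_dijkstra_path_length(
        simple, anchors, cutoff=hop_limit, weight=None
    )
    kept = set(dist)
    if drug not in kept:
        sub.unreachable = True
        kept = kept | {drug}

    sub.entities = kept
    sub.anchor_pathways = set(anchors) & kept
    sub.families = {n: neighborhood.family_of(n) for n in kept
                    if n in neighborhood}
    sub.families.setdefault(drug, "Compound")
    for h, t, data in neighborhood.graph.edges(data=True):
        if h in kept and t in kept:
            sub.edges.append((h, data["relation"], t))
    sub.relations = {rel for _, rel, _ in sub.edges}
    return sub


def verify_hop_guarantee(sub: DrugSubgraph, hop_limit: int = 4) -> bool:
    """Independent breadth-first check that the drug reaches an anchor pathway
    within the hop limit (used for audits; extraction must already ensure it).
    """
    if sub.unreachable:
        return False
    g = sub.to_graph()
    lengths = nx.single_source_shortest_path_length(g, sub.drug,
                                                    cutoff=hop_limit)
    return any(p in lengths for p in sub.anchor_pathways)


def consistency_filter(drug_table, ddi_table,
                       subgraphs: dict[str, DrugSubgraph]):
    """Remove drugs with no usable edges or no reachable pathway, and every
    interaction row touching a removed drug.

    Returns ``(filtered_drug_table, filtered_ddi_table, report)`` where
    ``report`` is a list of ``(drug_id, reason)`` pairs.
    """
    from .io import DrugTable, DDITable  # local import to avoid a cycle

    report: list[tuple[str, str]] = []
    keep: set[str] = set()
    for drug_id, _ in drug_table.records:
        sub = subgraphs.get(drug_id)
        if sub is None or not sub.has_usable_edges():
            report.append((drug_id, "no-usable-edges"))
        elif sub.unreachable:
            report.append((drug_id, "pathway-unreachable"))
        else:
            keep.add(drug_id)

    drugs = DrugTable([r for r in drug_table.records if r[0] in keep])
    ddis = DDITable([r for r in ddi_table.records
                     if r[0] in keep and r[1] in keep])
    return drugs, ddis, report
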