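"""Seeded generators for every input the pipeline consumes.

The generators emulate the study's four inputs at desk scale: a typed
knowledge graph with planted Drug–Gene–Pathway–Gene–Drug mediator paths, a
SMILES corpus (grammar-generated strings plus a fixed panel of real drug
molecules), interaction labels that are a deterministic function of the
planted pathway sharing (with an optional uniform flip noise), and embedding
stores that either are random or satisfy the translational property
``h + r ≈ t`` on true triples.

Planted mediator paths use exactly the gene-bridged motif, so the 4-hop
pathway-anchored extraction retains them, and tests that plant longer decoy
chains get sharp expected outcomes.  All outputs are reproducible from the
spec seed and are written in the package's standard formats, making
synthetic and real runs path-identical.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .io import DDITable, DrugTable, EmbeddingStore
from .kg import SELF_RELATION, HeteroKG
from .tokenizer import tokenize

# Fixed panel of real drug molecules: includes multi-character halogens,
# bracket atoms, charges, stereochemistry marks, fused rings.
DRUG_PANEL: tuple[tuple[str, str], ...] = (
    ("aspirin", "CC(=O)Oc1ccccc1C(=O)O"),
    ("paracetamol", "CC(=O)Nc1ccc(O)cc1"),
    ("caffeine", "Cn1cnc2c1c(=O)n(C)c(=O)n2C"),
    ("ibuprofen", "CC(C)Cc1ccc(cc1)C(C)C(=O)O"),
    ("nicotine", "CN1CCCC1c1cccnc1"),
    ("benzocaine", "CCOC(=O)c1ccc(N)cc1"),
    ("chlorzoxazone", "Clc1ccc2[nH]c(=O)oc2c1"),
    ("bromhexine-core", "Nc1c(Br)cc(Br)cc1CN"),
    ("imidazole", "c1c[nH]cn1"),
    ("nitrobenzene", "c1ccc(cc1)[N+](=O)[O-]"),
    ("alanine", "C[C@H](N)C(=O)O"),
    ("trans-2-butene", "C/C=C/C"),
    ("acetonitrile-deriv", "CC#N"),
    ("cyclopropane", "C1CC1"),
    ("thiophene", "c1ccsc1"),
    ("furanone", "O=C1CCO1"),
    ("pyridine-n-oxide", "[O-][n+]1ccccc1"),
    ("chlorobenzene", "Clc1ccccc1"),
    ("isoniazid-core", "NNC(=O)c1ccncc1"),
    ("valproate-core", "CCCC(CCC)C(=O)O"),
)

_RING_MOTIFS = ("c1ccccc1", "C1CCCCC1", "c1ccncc1", "c1cc[nH]c1",
                "C1CC1", "C1CCOC1", "c1ccsc1")
_CHAIN_ATOMS = ("C", "C", "C", "N", "O", "S")
_TERMINALS = ("Cl", "Br", "O", "N", "C")


@dataclass
class SyntheticSpec:
    """Study conditions for the synthetic generators."""

    n_drugs: int = 50
    n_pathways: int = 24
    n_diseases: int = 8
    n_side_effects: int = 8
    mediator_density: float = 0.3   # fraction of drug pairs sharing a bridge
    n_classes: int = 5
    n_pairs: int = 200
    noise: float = 0.0
    embedding_dim: int = 32
    decoy_edges_per_drug: int = 2
    pathway_zipf: float = 1.2       # long-tail exponent of mediator usage
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.noise < 0.5):
            raise ValueError("noise rate must lie in [0, 0.5)")
        for name in ("n_drugs", "n_pathways", "n_diseases",
                     "n_side_effects", "n_classes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class PlantedTruth:
    """Ground truth of the planted mediator structure."""

    pairs: list[tuple[str, str, str]] = field(default_factory=list)
    # (drug_a, drug_b, pathway), drug_a < drug_b
    pathways: list[str] = field(default_factory=list)

    def pathway_of(self, a: str, b: str) -> str | None:
        key = tuple(sorted((a, b)))
        for pa, pb, pw in self.pairs:
            if (pa, pb) == key:
                return pw
        return None


def _drug_id(i: int) -> str:
    return f"Compound::D{i:04d}"


def gen_kg(spec: SyntheticSpec) -> tuple[HeteroKG, PlantedTruth]:
    """Typed KG with planted Drug–Gene–Pathway–Gene–Drug mediators.

    Every drug gets a base anchor path Drug–Gene–Pathway so that no drug is
    pathway-unreachable by construction; planted interacting pairs share a
    dedicated mediator pathway through fresh bridge genes; decoy edges add
    heterogeneous clutter (gene–disease, drug–side-effect, gene–gene).
    """
    rng = np.random.default_rng(spec.seed)
    n_pairs_total = spec.n_drugs * (spec.n_drugs - 1) // 2
    n_planted = int(spec.mediator_density * n_pairs_total)
    if n_planted > n_pairs_total:
        raise ValueError("more planted pairs than drug pairs")

    kg = HeteroKG()
    truth = PlantedTruth()
    drugs = [_drug_id(i) for i in range(spec.n_drugs)]
    pathways = [f"Pathway::P{i:04d}" for i in range(spec.n_pathways)]
    diseases = [f"Disease::Z{i:04d}" for i in range(spec.n_diseases)]
    side_effects = [f"Side-effect::S{i:04d}"
                    for i in range(spec.n_side_effects)]
    truth.pathways = pathways
    gene_counter = itertools.count()

    def fresh_gene() -> str:
        return f"Gene::G{next(gene_counter):05d}"

    for node in drugs + pathways + diseases + side_effects:
        kg.add_node(node)

    # base anchor: Drug - Gene - Pathway (keeps every drug reachable)
    base_genes = {}
    for i, drug in enumerate(drugs):
        gene = fresh_gene()
        base_genes[drug] = gene
        kg.add_triple(drug, "targets", gene)
        kg.add_triple(gene, "member_of", pathways[i % spec.n_pathways])

    # planted mediators; pathway usage follows a long-tail (Zipf-like)
    # distribution, mirroring the pronounced imbalance of real interaction
    # data where a few pathways mediate many pairs
    all_pairs = list(itertools.combinations(range(spec.n_drugs), 2))
    chosen = rng.choice(len(all_pairs), size=n_planted, replace=False)
    usage = 1.0 / np.arange(1, spec.n_pathways + 1) ** spec.pathway_zipf
    usage /= usage.sum()
    for pair_idx in sorted(chosen):
        ia, ib = all_pairs[pair_idx]
        a, b = drugs[ia], drugs[ib]
        pathway = pathways[int(rng.choice(spec.n_pathways, p=usage))]
        ga, gb = fresh_gene(), fresh_gene()
        kg.add_triple(a, "targets", ga)
        kg.add_triple(ga, "member_of", pathway)
        kg.add_triple(b, "targets", gb)
        kg.add_triple(gb, "member_of", pathway)
        truth.pairs.append((*sorted((a, b)), pathway))

    # heterogeneous decoys; none connects two drug neighborhoods directly,
    # so pathway sharing stays the only planted cross-drug structure
    for drug in drugs:
        for _ in range(spec.decoy_edges_per_drug):
            kind = rng.integers(3)
            if kind == 0:
                kg.add_triple(base_genes[drug], "associates",
                              diseases[int(rng.integers(len(diseases)))])
            elif kind == 1:
                kg.add_triple(drug, "causes",
                              side_effects[int(rng.integers(len(side_effects)))])
            else:
                kg.add_triple(drug, "targets", fresh_gene())  # dead-end gene
    return kg, truth


def gen_smiles(n: int, rng_seed: int = 0) -> DrugTable:
    """n unique, parseable SMILES: the fixed drug panel first, then
    grammar-generated strings.  Every emitted string round-trips through the
    tokenizer (cover property), asserted at generation time."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng_seed)
    strings: list[str] = []
    seen: set[str] = set()
    for _, smiles in DRUG_PANEL[:n]:
        strings.append(smiles)
        seen.add(smiles)
    while len(strings) < n:
        s = _random_smiles(rng)
        if s not in seen:
            seen.add(s)
            strings.append(s)
    for s in strings:
        assert "".join(tokenize(s)) == s
    return DrugTable([(_drug_id(i), s) for i, s in enumerate(strings)])


def _random_chain(rng: np.random.Generator, length: int) -> str:
    parts = []
    for i in range(length):
        if i and rng.random() < 0.15:
            parts.append("=")
        parts.append(_CHAIN_ATOMS[rng.integers(len(_CHAIN_ATOMS))])
        if rng.random() < 0.25:
            inner = _TERMINALS[rng.integers(len(_TERMINALS))]
            parts.append(f"({inner})")
    return "".join(parts)


def _random_smiles(rng: np.random.Generator) -> str:
    chain = _random_chain(rng, int(rng.integers(2, 7)))
    if rng.random() < 0.6:
        motif = _RING_MOTIFS[rng.integers(len(_RING_MOTIFS))]
        return chain + motif
    return chain


def gen_ddi(truth: PlantedTruth, spec: SyntheticSpec) -> DDITable:
    """Labels as a deterministic function of planted structure: a planted
    pair's class is ``1 + (pathway index mod (n_classes - 1))``; sampled
    non-planted pairs take class 0; labels then flip to a random other class
    with probability ``spec.noise``."""
    rng = np.random.default_rng(spec.seed + 1)
    pathway_index = {p: i for i, p in enumerate(truth.pathways)}
    records: list[tuple[str, str, int]] = []
    planted_keys = set()
    # keep at most ~3/4 of the table for planted (positive) pairs so the
    # no-interaction class always has support
    planted = list(truth.pairs)
    n_pos = min(len(planted), max(int(round(0.75 * spec.n_pairs)), 1))
    if n_pos < len(planted):
        keep_idx = sorted(rng.choice(len(planted), size=n_pos, replace=False))
        planted = [planted[i] for i in keep_idx]
    for a, b, pathway in planted:
        label = 1 + pathway_index[pathway] % max(spec.n_classes - 1, 1)
        records.append((a, b, label))
    for a, b, _ in truth.pairs:
        planted_keys.add((a, b))

    drugs = [_drug_id(i) for i in range(spec.n_drugs)]
    negatives = [tuple(sorted((a, b)))
                 for a, b in itertools.combinations(drugs, 2)
                 if tuple(sorted((a, b))) not in planted_keys]
    n_neg = max(spec.n_pairs - len(records), 0)
    if n_neg and negatives:
        idx = rng.choice(len(negatives), size=min(n_neg, len(negatives)),
                         replace=False)
        for i in sorted(idx):
            a, b = negatives[i]
            records.append((a, b, 0))

    if spec.noise > 0:
        flips = rng.random(len(records)) < spec.noise
        for i, flip in enumerate(flips):
            if flip:
                a, b, label = records[i]
                other = int(rng.integers(spec.n_classes - 1))
                if other >= label:
                    other += 1
                records[i] = (a, b, other)
    return DDITable(records)


def gen_embeddings(kg: HeteroKG, dim: int, mode: str = "translational",
                   rng_seed: int = 0, n_families: int = 4) -> EmbeddingStore:
    """Embedding store over all KG entities and relation types (plus the
    self-loop relation).

    ``random``: i.i.d. Gaussian vectors.  ``translational``: Gaussian entity
    vectors with each relation vector set to the mean of ``t - h`` over its
    true triples, so ``h + r - t`` has small norm on true triples.  In both
    modes, pathway entities of the same functional family (pathway index
    modulo ``n_families``) share a family centroid plus noise — pretrained
    biomedical embeddings place functionally related pathways near each
    other, and downstream consumers may rely on that structure.
    """
    if dim < 2:
        raise ValueError("dim must be >= 2")
    rng = np.random.default_rng(rng_seed)
    scale = 1.0 / np.sqrt(dim)
    entities = sorted(kg.graph.nodes)
    relations = sorted({d["relation"]
                       for _, _, d in kg.graph.edges(data=True)}
                      | {SELF_RELATION})
    table = {e: rng.normal(0.0, scale, dim) for e in entities}
    pathways = sorted(e for e in entities
                      if kg.family_of(e) == "Pathway")
    centroids = rng.normal(0.0, scale, (n_families, dim))
    for i, p in enumerate(pathways):
        table[p] = centroids[i % n_families] + rng.normal(0.0, 0.3 * scale,
                                                          dim)
    if mode == "random":
        for r in relations:
            table[r] = rng.normal(0.0, scale, dim)
    elif mode == "translational":
        sums = {r: np.zeros(dim) for r in relations}
        counts = {r: 0 for r in relations}
        for h, r, t in kg.triples():
            sums[r] += table[t] - table[h]
            counts[r] += 1
        for r in relations:
            if counts[r]:
                table[r] = sums[r] / counts[r]
            else:
                table[r] = np.zeros(dim)   # self-relation: exact translation
    else:
        raise ValueError(f"unknown embedding mode {mode!r}")
    return EmbeddingStore(table)


# ---------------------------------------------------------------------------
# interpretability scenarios (anchor + partner subgraphs, built directly)


def gen_screen_case(n_interacting: int = 6, n_noninteracting: int = 6,
                    rng_seed: int = 0, effect: bool = True):
    """Anchor-screening scenario with a planted bridging pathway.

    With ``effect=True``, interacting partners connect to the anchor
    *through* the planted pathway (several gene spokes each), making it a
    high-betweenness bridge in their merged subgraphs; noninteracting
    partners carry the planted pathway only as a peripheral leaf and reach
    the anchor neighborhood through a shared hub gene instead.  With
    ``effect=False`` all partners use the peripheral wiring, so group labels
    carry no signal (the null scenario for type-I checks).

    Returns ``(subgraphs, ddi_table, anchor_id, planted_pathway)`` where
    interacting pairs carry label 1 and noninteracting pairs label 0.
    """
    from .kg import DrugSubgraph

    rng = np.random.default_rng(rng_seed)
    planted = "Pathway::P_planted"
    null_pw = "Pathway::P_null"
    anchor = "Compound::ANCHOR"
    hub = "Gene::HUB"

    def leaf_genes(tag: str, n: int) -> list[str]:
        return [f"Gene::{tag}{i}" for i in range(n)]

    def family_map(nodes):
        return {n: n.split("::")[0].replace("Side-effect", "SideEffect")
                for n in nodes}

    def build(drug, edges):
        nodes = {drug}
        triple_list = []
        for u, v in edges:
            nodes.update((u, v))
            triple_list.append((u, "rel", v))
        return DrugSubgraph(
            drug=drug, entities=nodes,
            relations={"rel"},
            anchor_pathways={n for n in nodes if n.startswith("Pathway")},
            edges=triple_list, families=family_map(nodes),
        )

    a_genes = leaf_genes("A", 3)
    anchor_edges = [(anchor, a_genes[0]), (a_genes[0], planted),
                    (anchor, a_genes[1]), (a_genes[1], planted),
                    (anchor, a_genes[2]), (a_genes[2], null_pw),
                    (anchor, hub)]
    subgraphs = {anchor: build(anchor, anchor_edges)}
    ddi_records = []

    def bridged_partner(drug, tag):
        # partner reaches the anchor side only through the planted pathway
        spokes = leaf_genes(tag, 2 + int(rng.integers(2)))
        edges = []
        for g in spokes:
            edges.append((drug, g))
            edges.append((g, planted))
        edges.append((drug, f"Gene::{tag}x"))
        edges.append((f"Gene::{tag}x", null_pw))
        return build(drug, edges)

    def peripheral_partner(drug, tag):
        # planted pathway is a leaf; the anchor is reached via the hub gene
        chain = leaf_genes(tag, 2 + int(rng.integers(3)))
        edges = [(drug, hub), (drug, chain[0])]
        for u, v in zip(chain, chain[1:]):
            edges.append((u, v))
        edges.append((chain[-1], planted))
        edges.append((drug, f"Gene::{tag}x"))
        edges.append((f"Gene::{tag}x", null_pw))
        return build(drug, edges)

    for i in range(n_interacting):
        drug = f"Compound::INT{i}"
        maker = bridged_partner if effect else peripheral_partner
        subgraphs[drug] = maker(drug, f"I{i}_")
        ddi_records.append((anchor, drug, 1))
    for i in range(n_noninteracting):
        drug = f"Compound::NON{i}"
        subgraphs[drug] = peripheral_partner(drug, f"N{i}_")
        ddi_records.append((anchor, drug, 0))

    return subgraphs, DDITable(ddi_records), anchor, planted
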