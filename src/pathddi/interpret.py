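"""Post-hoc pathway-level interpretability.

Two drug-centered subgraphs are merged; a pathway node shared by both
subgraphs is the candidate mediating context (only a shared pathway makes
the Drug A–Pathway X–Drug B pattern an actual connection).  Within each
merged graph, four complementary centralities quantify the pathway's
topological prominence: degree (local connectivity), betweenness (presence
on shortest routes between the drug neighborhoods), closeness (reach
efficiency), and eigenvector centrality (influence through well-connected
neighbors).

For one anchor drug and interaction label, pathway centralities are sampled
across interacting and noninteracting partner drugs, then screened:

1. coverage filter — the pathway must appear in at least ``coverage_min``
   of the interacting partners' subgraphs;
2. two-sided Mann–Whitney U per centrality;
3. Benjamini–Hochberg FDR correction across the whole
   (pathway x centrality) hypothesis family of the anchor;
4. effect-direction consistency — every significant centrality must shift
   toward the interacting group — plus a Cliff's-delta floor;
5. survivors are ranked by the weighted separation score
   ``sum_c REP_W[c] * SMD_c`` with the fixed centrality weights
   ``{betweenness 0.40, eigenvector 0.30, degree 0.20, closeness 0.10}``
   and ties broken lexicographically by pathway identifier.

The separation statistic feeding the weights is the standardized mean
difference (mean difference over pooled standard deviation).  Screening is
strictly post hoc: it consumes predictions and graphs, never feeding back
into training.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import DDITable
from .kg import DrugSubgraph

CENTRALITY_ORDER = ("betweenness", "eigenvector", "degree", "closeness")
REP_W = {"betweenness": 0.40, "eigenvector": 0.30,
         "degree": 0.20, "closeness": 0.10}
_SMD_CAP = 10.0   # standardized mean difference under zero pooled spread


# ---------------------------------------------------------------------------
# merged subgraphs and centralities


@dataclass
class MergedSubgraph:
    graph: nx.Graph
    drug_a: str
    drug_b: str
    shared_pathways: set[str]
    node_origin: dict[str, str]          # "a" | "b" | "shared"

    @property
    def connected_via_pathway(self) -> bool:
        return bool(self.shared_pathways)

    def to_json_dict(self) -> dict:
        return {
            "drug_a": self.drug_a,
            "drug_b": self.drug_b,
            "shared_pathways": sorted(self.shared_pathways),
            "connected_via_pathway": self.connected_via_pathway,
            "nodes": [
                {"id": n, "origin": self.node_origin[n],
                 "family": self.graph.nodes[n].get("family", "Other")}
                for n in sorted(self.graph.nodes)
            ],
            "edges": [[u, v] for u, v in sorted(map(sorted, self.graph.edges))],
        }


def merge_subgraphs(sub_a: DrugSubgraph, sub_b: DrugSubgraph) -> MergedSubgraph:
    """Union of two drug subgraphs with origin coloring and shared-pathway
    detection."""
    ga, gb = sub_a.to_graph(), sub_b.to_graph()
    merged = nx.compose(ga, gb)
    origin = {}
    for node in merged.nodes:
        in_a, in_b = node in ga, node in gb
        origin[node] = "shared" if (in_a and in_b) else ("a" if in_a else "b")
    shared_pathways = {
        n for n in merged.nodes
        if merged.nodes[n].get("family") == "Pathway"
        and n in ga and n in gb
    }
    return MergedSubgraph(graph=merged, drug_a=sub_a.drug, drug_b=sub_b.drug,
                          shared_pathways=shared_pathways, node_origin=origin)


def centralities(graph: nx.Graph, nodes=None) -> dict[str, dict[str, float]]:
    """All four centralities per node (normalized conventions: degree by
    ``n - 1``, betweenness by pair count, closeness per component,
    eigenvector unit-norm per component by power iteration)."""
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    deg = nx.degree_centrality(graph)
    bet = nx.betweenness_centrality(graph, normalized=True)
    clo = nx.closeness_centrality(graph)
    eig: dict[str, float] = {}
    for comp in nx.connected_components(graph):
        sub = graph.subgraph(comp)
        if len(comp) == 1:
            eig[next(iter(comp))] = 1.0
            continue
        eig.update(nx.eigenvector_centrality(sub, max_iter=10_000, tol=1e-8))
    wanted = graph.nodes if nodes is None else nodes
    return {
        n: {"degree": deg[n], "betweenness": bet[n],
            "closeness": clo[n], "eigenvector": eig[n]}
        for n in wanted
    }


# ---------------------------------------------------------------------------
# partner-group sampling


@dataclass
class PathwaySamples:
    """Per-pathway centrality samples across the two partner groups."""

    pathway: str
    interacting: list[dict[str, float]] = field(default_factory=list)
    noninteracting: list[dict[str, float]] = field(default_factory=list)
    n_interacting_partners: int = 0
    non_covering_interacting: int = 0

    @property
    def coverage(self) -> float:
        if self.n_interacting_partners == 0:
            return 0.0
        return len(self.interacting) / self.n_interacting_partners

    def samples(self, group: str, centrality: str) -> np.ndarray:
        rows = self.interacting if group == "interacting" else self.noninteracting
        return np.array([r[centrality] for r in rows], dtype=np.float64)


def partner_group_distributions(anchor: str, label: int, ddi: DDITable,
                                subgraphs: dict[str, DrugSubgraph]
                                ) -> tuple[list[str], list[str],
                                           dict[str, PathwaySamples]]:
    """Partner groups of one anchor drug and the per-pathway centrality
    samples over their merged subgraphs.

    Interacting partners are those paired with the anchor under ``label``;
    noninteracting partners are those paired under label 0 (the
    no-interaction class).  Candidate pathways are the anchor subgraph's
    pathway nodes; a partner whose subgraph lacks the pathway counts against
    coverage only.
    """
    if label == 0:
        raise ValueError("label 0 is the noninteracting class")
    interacting, noninteracting = [], []
    for a, b, lab in ddi.records:
        if anchor not in (a, b):
            continue
        partner = b if a == anchor else a
        if partner not in subgraphs or partner == anchor:
            continue
        if lab == label:
            interacting.append(partner)
        elif lab == 0:
            noninteracting.append(partner)
    if not interacting or not noninteracting:
        raise ValueError(
            f"anchor {anchor!r} needs both partner groups "
            f"(interacting: {len(interacting)}, "
            f"noninteracting: {len(noninteracting)})"
        )

    anchor_sub = subgraphs[anchor]
    candidates = {n for n in anchor_sub.entities
                  if anchor_sub.families.get(n) == "Pathway"}
    samples = {p: PathwaySamples(pathway=p,
                                 n_interacting_partners=len(interacting))
               for p in sorted(candidates)}
    for group, partners in (("interacting", interacting),
                            ("noninteracting", noninteracting)):
        for partner in partners:
            merged = merge_subgraphs(anchor_sub, subgraphs[partner])
            present = {p for p in candidates
                       if p in subgraphs[partner].entities}
            if present:
                cents = centralities(merged.graph, nodes=present)
            for p in sorted(candidates):
                rec = samples[p]
                if p in present:
                    getattr(rec, group).append(cents[p])
                elif group == "interacting":
                    rec.non_covering_interacting += 1
    return interacting, noninteracting, samples


# ---------------------------------------------------------------------------
# screening


def cliffs_delta(x: np.ndarray, y: np.ndarray) -> float:
    """Cliff's delta of x over y in [-1, 1]; 1 means complete dominance."""
    x = np.asarray(x, dtype=np.float64)[:, None]
    y = np.asarray(y, dtype=np.float64)[None, :]
    return float((np.sign(x - y)).mean())


def standardized_mean_difference(x: np.ndarray, y: np.ndarray) -> float:
    diff = float(np.mean(x) - np.mean(y))
    nx_, ny_ = len(x), len(y)
    pooled_var = (
        ((nx_ - 1) * np.var(x, ddof=1) if nx_ > 1 else 0.0)
        + ((ny_ - 1) * np.var(y, ddof=1) if ny_ > 1 else 0.0)
    ) / max(nx_ + ny_ - 2, 1)
    pooled_sd = math.sqrt(pooled_var)
    if pooled_sd == 0.0:
        return 0.0 if diff == 0.0 else math.copysign(_SMD_CAP, diff)
    return diff / pooled_sd


def weighted_separation(separations, coverage: float | None = None,
                        eigenvector_emphasis: float = 0.0,
                        weights: dict[str, float] = REP_W) -> float:
    """Fixed-weight combination of the four per-centrality separations, in
    the order (betweenness, eigenvector, degree, closeness); optionally
    multiplied by coverage and an eigenvector-prominence bonus."""
    seps = dict(zip(CENTRALITY_ORDER, separations))
    score = sum(weights[c] * seps[c] for c in CENTRALITY_ORDER)
    if coverage is not None:
        score *= coverage
    if eigenvector_emphasis:
        score *= 1.0 + eigenvector_emphasis * max(seps["eigenvector"], 0.0)
    return float(score)


@dataclass
class CentralityStats:
    mean_diff: float | None = None
    median_diff: float | None = None
    u_stat: float | None = None
    p: float | None = None
    q: float | None = None
    delta: float | None = None
    smd: float = 0.0
    significant: bool = False
    skipped: str | None = None


@dataclass
class PathwayScreenRecord:
    anchor: str
    pathway: str
    coverage: float
    stats: dict[str, CentralityStats]
    weighted_score: float = 0.0
    passed: bool = False
    fail_reasons: list[str] = field(default_factory=list)

    def to_row(self) -> dict:
        row = {"anchor": self.anchor, "pathway": self.pathway,
               "coverage": round(self.coverage, 4),
               "weighted_score": round(self.weighted_score, 6),
               "passed": self.passed}
        for c in CENTRALITY_ORDER:
            s = self.stats[c]
            row[f"{c}_p"] = s.p
            row[f"{c}_q"] = s.q
            row[f"{c}_delta"] = s.delta
            row[f"{c}_smd"] = s.smd
        return row


def screen_pathways(anchor: str, samples: dict[str, PathwaySamples],
                    coverage_min: float = 0.3, alpha: float = 0.05,
                    delta_min: float = 0.147,
                    weights: dict[str, float] = REP_W
                    ) -> list[PathwayScreenRecord]:
    """Run the full screen; returns records with survivors ranked first by
    weighted separation score (descending), ties broken by pathway ID."""
    if not samples:
        raise ValueError("no pathway records to screen")
    records: dict[str, PathwayScreenRecord] = {}
    hypotheses: list[tuple[str, str, float]] = []
    for pathway in sorted(samples):
        rec_samples = samples[pathway]
        stats_by_c: dict[str, CentralityStats] = {}
        for c in CENTRALITY_ORDER:
            xi = rec_samples.samples("interacting", c)
            yi = rec_samples.samples("noninteracting", c)
            cs = CentralityStats()
            if len(xi) < 2 or len(yi) < 2:
                cs.skipped = "group-too-small"
            else:
                cs.mean_diff = float(xi.mean() - yi.mean())
                cs.median_diff = float(np.median(xi) - np.median(yi))
                if np.ptp(np.concatenate([xi, yi])) == 0.0:
                    cs.u_stat = float(len(xi) * len(yi) / 2.0)
                    cs.p = 1.0
                else:
                    u, p = stats.mannwhitneyu(xi, yi,
                                              alternative="two-sided")
                    cs.u_stat, cs.p = float(u), float(p)
                cs.delta = cliffs_delta(xi, yi)
                cs.smd = standardized_mean_difference(xi, yi)
                hypotheses.append((pathway, c, cs.p))
            stats_by_c[c] = cs
        records[pathway] = PathwayScreenRecord(
            anchor=anchor, pathway=pathway,
            coverage=rec_samples.coverage, stats=stats_by_c,
        )

    # BH across the full (pathway x centrality) family of this anchor
    if hypotheses:
        pvals = [p for _, _, p in hypotheses]
        _, qvals, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
        for (pathway, c, _), q in zip(hypotheses, qvals):
            s = records[pathway].stats[c]
            s.q = float(q)
            s.significant = bool(q <= alpha)

    for rec in records.values():
        rec.weighted_score = weighted_separation(
            [rec.stats[c].smd for c in CENTRALITY_ORDER]
        )
        sig = [rec.stats[c] for c in CENTRALITY_ORDER
               if rec.stats[c].significant]
        if rec.coverage < coverage_min:
            rec.fail_reasons.append("coverage")
        if not sig:
            rec.fail_reasons.append("no-significant-centrality")
        if any(s.mean_diff is None or s.mean_diff <= 0 for s in sig):
            rec.fail_reasons.append("direction")
        if any(s.delta is None or s.delta < delta_min for s in sig):
            rec.fail_reasons.append("effect-size")
        rec.passed = not rec.fail_reasons

    return sorted(
        records.values(),
        key=lambda r: (not r.passed, -r.weighted_score, r.pathway),
    )


# ---------------------------------------------------------------------------
# distribution summaries (descriptive, for the KDE-style figures)


@dataclass
class DistributionSummary:
    grid: np.ndarray | None
    density_interacting: np.ndarray | None
    density_noninteracting: np.ndarray | None
    percentile_95: float
    rug_points: np.ndarray
    mean_difference: float
    degenerate: bool = False


def distribution_summary(interacting: np.ndarray, noninteracting: np.ndarray,
                         n_grid: int = 200) -> DistributionSummary:
    """Kernel-density summaries per group with the pooled 95th percentile
    (linear-interpolation order statistic) and the rug of points above it.
    Constant samples degenerate the KDE; a histogram-free summary with a
    warning flag is returned instead."""
    xi = np.asarray(interacting, dtype=np.float64)
    yi = np.asarray(noninteracting, dtype=np.float64)
    if len(xi) < 2 or len(yi) < 2:
        raise ValueError("need at least 2 points per group")
    pooled = np.concatenate([xi, yi])
    p95 = float(np.percentile(pooled, 95, method="linear"))
    rug = np.sort(pooled[pooled > p95])
    mean_diff = float(xi.mean() - yi.mean())
    if np.ptp(pooled) == 0.0 or np.ptp(xi) == 0.0 or np.ptp(yi) == 0.0:
        return DistributionSummary(None, None, None, p95, rug, mean_diff,
                                   degenerate=True)
    grid = np.linspace(pooled.min(), pooled.max(), n_grid)
    kde_i = stats.gaussian_kde(xi)(grid)
    kde_n = stats.gaussian_kde(yi)(grid)
    return DistributionSummary(grid, kde_i, kde_n, p95, rug, mean_diff)


def plot_distribution_summary(summary: DistributionSummary, path,
                              title: str = "") -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.2))
    if not summary.degenerate:
        ax.plot(summary.grid, summary.density_interacting,
                color="crimson", label="interacting")
        ax.plot(summary.grid, summary.density_noninteracting,
                color="steelblue", label="noninteracting")
    ax.axvline(summary.percentile_95, color="gray", linestyle="--",
               label="95th percentile")
    if len(summary.rug_points):
        ax.plot(summary.rug_points,
                np.zeros_like(summary.rug_points), "|", color="black")
    ax.set_xlabel("centrality score")
    ax.set_ylabel("density")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
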