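"""Correlation networks, Louvain communities, project similarity, and
betweenness-centrality knowledge summarization.

The correlation network connects features whose pairwise coefficient
exceeds the inclusion threshold (signed by default, matching the printed
rule "coefficient > 0.5"; an absolute-value mode is available) at
BH-adjusted p below the FDR bound.  The knowledge summary expands one hop
from the regulated proteins into the prior-knowledge graph (diseases,
drugs, pathways, processes, publications, and kinases via substrate edges)
and keeps, per node label, the top-k nodes by exact shortest-path
betweenness (unweighted undirected view, unnormalized pair counts,
endpoints excluded) — ties broken by node id.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .graph_store import PropertyGraph
from .prep import ExperimentMatrix
from .stats import bh_fdr

__all__ = [
    "CorrelationNetwork",
    "KnowledgeSummary",
    "correlation_network",
    "louvain_communities",
    "project_similarity",
    "betweenness_centrality",
    "betweenness_topk",
    "build_knowledge_subgraph",
]

DEFAULT_SUMMARY_LABELS = (
    "Disease", "Drug", "Pathway", "Biological_process", "Publication", "Complex", "Protein",
)


@dataclass
class CorrelationNetwork:
    edges: pd.DataFrame  # source, target, coefficient, pvalue, padj
    graph: nx.Graph
    clusters: dict  # node -> community id
    modularity: float
    method: str
    excluded: list = field(default_factory=list)  # constant features


def _corr_pvalues(r: np.ndarray, n: int) -> np.ndarray:
    r = np.clip(r, -0.9999999999, 0.9999999999)
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return 2.0 * sps.t.sf(np.abs(t), df=n - 2)


def correlation_network(matrix: ExperimentMatrix, method: str = "pearson",
                        min_coefficient: float = 0.5, fdr_max: float = 0.05,
                        blocks: tuple | None = None, absolute: bool = False,
                        seed: int = 0) -> CorrelationNetwork:
    """Pairwise feature correlation network with BH-filtered edges.

    ``blocks``: optional (features_a, features_b) bipartite restriction —
    only cross-block pairs are tested (the clinical-vs-protein network).
    Edge rule: coefficient > min_coefficient (signed, or |coefficient| with
    ``absolute``) and adjusted p < fdr_max.  Isolated nodes are dropped;
    Louvain communities are attached.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    values = matrix.values
    if values.isna().any().any():
        raise ValueError("matrix contains missing values; run impute() first")
    if values.shape[0] < 3:
        raise ValueError("need >= 3 samples for correlation analysis")
    sds = values.std(axis=0, ddof=1)
    excluded = list(values.columns[sds == 0])
    if excluded:
        warnings.warn(f"excluding constant features: {excluded}")
        values = values.drop(columns=excluded)
    data = values.rank(axis=0) if method == "spearman" else values
    features = list(values.columns)
    corr = np.corrcoef(data.to_numpy(dtype=float), rowvar=False)
    n = values.shape[0]
    ix = {f: i for i, f in enumerate(features)}
    if blocks is not None:
        block_a = [f for f in blocks[0] if f in ix]
        block_b = [f for f in blocks[1] if f in ix]
        pairs = [(a, b) for a in block_a for b in block_b if a != b]
    else:
        pairs = [(features[i], features[j]) for i in range(len(features))
                 for j in range(i + 1, len(features))]
    if not pairs:
        empty = pd.DataFrame(columns=["source", "target", "coefficient", "pvalue", "padj"])
        return CorrelationNetwork(edges=empty, graph=nx.Graph(), clusters={},
                                  modularity=0.0, method=method, excluded=excluded)
    coefs = np.array([corr[ix[a], ix[b]] for a, b in pairs])
    pvals = _corr_pvalues(coefs, n)
    padj = bh_fdr(pvals)
    table = pd.DataFrame({
        "source": [a for a, _ in pairs], "target": [b for _, b in pairs],
        "coefficient": coefs, "pvalue": pvals, "padj": padj,
    })
    strength = table["coefficient"].abs() if absolute else table["coefficient"]
    kept = table[(strength > min_coefficient) & (table["padj"] < fdr_max)].reset_index(drop=True)
    g = nx.Graph()
    for row in kept.itertuples(index=False):
        g.add_edge(row.source, row.target, weight=abs(row.coefficient),
                   coefficient=row.coefficient, padj=row.padj)
    clusters, q = louvain_communities(g, seed=seed)
    return CorrelationNetwork(edges=kept, graph=g, clusters=clusters, modularity=q,
                              method=method, excluded=excluded)


def louvain_communities(graph: nx.Graph, resolution: float = 1.0, seed: int = 0):
    """Louvain partition and its modularity Q (deterministic under seed).

    Edgeless graphs yield singleton communities with Q = 0.  Community ids
    are renumbered by smallest member node for stable output.
    """
    if graph.number_of_edges() == 0:
        return {n: i for i, n in enumerate(sorted(graph.nodes, key=str))}, 0.0
    parts = nx.community.louvain_communities(graph, resolution=resolution, seed=seed,
                                             weight="weight")
    q = nx.community.modularity(graph, parts, weight="weight", resolution=resolution)
    ordered = sorted(parts, key=lambda c: min(map(str, c)))
    clusters = {}
    for i, community in enumerate(ordered):
        for node in community:
            clusters[node] = i
    return clusters, float(q)


@dataclass(frozen=True)
class ProjectSimilarity:
    jaccard: float
    overlap: float
    pearson: float  # NaN sentinel when < 3 shared proteins


def project_similarity(proteins_a, proteins_b, profile_a: pd.Series | None = None,
                       profile_b: pd.Series | None = None) -> ProjectSimilarity:
    """Identified-protein overlap (Jaccard, overlap coefficient) and mean
    profile correlation over shared proteins (NaN when fewer than 3)."""
    a, b = set(proteins_a), set(proteins_b)
    if not a and not b:
        raise ValueError("both protein sets are empty")
    inter = a & b
    jaccard = len(inter) / len(a | b)
    overlap = len(inter) / min(len(a), len(b)) if a and b else 0.0
    pearson = float("nan")
    if profile_a is not None and profile_b is not None and len(inter) >= 3:
        shared = sorted(inter)
        x = profile_a.loc[shared].to_numpy(dtype=float)
        y = profile_b.loc[shared].to_numpy(dtype=float)
        if np.std(x) > 0 and np.std(y) > 0:
            pearson = float(np.corrcoef(x, y)[0, 1])
    return ProjectSimilarity(jaccard=jaccard, overlap=overlap, pearson=pearson)


# ---------------------------------------------------------------------------
# knowledge summarization
# ---------------------------------------------------------------------------


@dataclass
class KnowledgeSummary:
    subgraph: PropertyGraph
    ranking: pd.DataFrame  # node, label, betweenness, retained
    retained: dict  # label -> ordered node list
    sankey: pd.DataFrame  # source_label, target_label, weight
    edge_table: pd.DataFrame = None  # source, source_label, target, target_label, type


def betweenness_centrality(graph: PropertyGraph) -> dict:
    """Exact unnormalized betweenness on the undirected simple view."""
    g = nx.Graph()
    g.add_nodes_from(graph.node_ids)
    for s, t, _ty, _a in graph.edges:
        if s != t:
            g.add_edge(s, t)
    return nx.betweenness_centrality(g, normalized=False)


def betweenness_topk(graph: PropertyGraph, k_per_label: int = 15,
                     always_keep=()) -> KnowledgeSummary:
    """Per-label top-k nodes by betweenness (ties broken by node id)."""
    if k_per_label < 1:
        raise ValueError("k_per_label must be >= 1")
    centrality = betweenness_centrality(graph)
    ranking = pd.DataFrame({
        "node": list(centrality),
        "label": [graph.label_of(n) for n in centrality],
        "betweenness": list(centrality.values()),
    }).sort_values(["label", "betweenness", "node"],
                   ascending=[True, False, True], kind="mergesort")
    always = set(always_keep)
    retained = {}
    keep_nodes = set()
    for label, sub in ranking.groupby("label", sort=True):
        # cap applies to free candidates; pinned nodes are always kept
        pinned = [n for n in sub["node"] if n in always]
        free = [n for n in sub["node"] if n not in always]
        chosen = pinned + free[:k_per_label]
        retained[label] = chosen
        keep_nodes.update(chosen)
    ranking["retained"] = ranking["node"].isin(keep_nodes)
    sub = graph.induced_subgraph(keep_nodes)
    edge_table = pd.DataFrame(
        [(s, graph.label_of(s), t, graph.label_of(t), ty) for s, t, ty, _ in sub.edges],
        columns=["source", "source_label", "target", "target_label", "type"],
    )
    if len(edge_table):
        sankey = (edge_table.groupby(["source_label", "target_label"])
                  .size().reset_index(name="weight"))
    else:
        sankey = pd.DataFrame(columns=["source_label", "target_label", "weight"])
    return KnowledgeSummary(subgraph=sub, ranking=ranking.reset_index(drop=True),
                            retained=retained, sankey=sankey, edge_table=edge_table)


def build_knowledge_subgraph(graph: PropertyGraph, regulated_proteins,
                             labels=DEFAULT_SUMMARY_LABELS,
                             k_per_label: int = 15) -> KnowledgeSummary:
    """Knowledge summary around the regulated proteins.

    One-hop expansion from the regulated proteins to the target labels
    (Protein neighbors only through substrate edges, i.e. upstream
    kinases), then per-label betweenness pruning on the expanded subgraph;
    the regulated proteins themselves are always retained.  Absent protein
    ids are skipped with a warning.
    """
    labels = set(labels)
    seeds = [p for p in regulated_proteins if p in graph]
    missing = sorted(set(regulated_proteins) - set(seeds))
    if missing:
        warnings.warn(f"regulated proteins absent from graph: {missing}")
    if not seeds:
        warnings.warn("empty regulated protein set: returning empty summary")
        empty = PropertyGraph(schema=graph.schema)
        return KnowledgeSummary(
            subgraph=empty,
            ranking=pd.DataFrame(columns=["node", "label", "betweenness", "retained"]),
            retained={},
            sankey=pd.DataFrame(columns=["source_label", "target_label", "weight"]),
            edge_table=pd.DataFrame(
                columns=["source", "source_label", "target", "target_label", "type"]),
        )
    keep = set(seeds)
    for seed in seeds:
        for nbr, ty in graph.neighbors(seed, direction="both"):
            lab = graph.label_of(nbr)
            if lab == "Protein":
                if ty == "IS_SUBSTRATE_OF" and lab in labels:
                    keep.add(nbr)
            elif lab in labels:
                keep.add(nbr)
    expanded = graph.induced_subgraph(keep)
    return betweenness_topk(expanded, k_per_label=k_per_label, always_keep=seeds)
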