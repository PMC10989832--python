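"""Co-occurrence networks and keystone-taxa ranking.

Edges are Spearman correlations between taxa passing both an |r| and a p
threshold (defaults r > 0.6, p < 0.05); keystones are the taxa topping
PageRank or eigenvector centrality on the |r|-weighted graph, the usual
reading of network hubs in microbial ecology.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, InsufficientDataError
from .commstats import relative_abundance

__all__ = [
    "CooccurrenceNetwork",
    "TopologyStats",
    "KeystoneRanking",
    "build_network",
    "topology_stats",
    "keystone_rank",
]


@dataclass
class CooccurrenceNetwork:
    graph: nx.Graph                 # nodes = taxa; edge attrs r, p, weight=|r|, sign
    edges: pd.DataFrame             # taxon_a, taxon_b, r, p
    r_threshold: float
    p_threshold: float

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)


def build_network(table: pd.DataFrame, r_threshold: float = 0.6,
                  p_threshold: float = 0.05,
                  min_prevalence: float = 0.0) -> CooccurrenceNetwork:
    """Spearman co-occurrence network on relative abundances.

    Taxa present in fewer than ``min_prevalence`` (fraction) of samples
    are dropped first; an edge is kept when |r| >= r_threshold and
    p <= p_threshold.  Edge weight is |r|, sign retained as an attribute.
    """
    if len(table) < 4:
        raise InsufficientDataError("correlation network needs >= 4 samples")
    rel = relative_abundance(table)
    prevalence = (table > 0).mean(axis=0)
    kept = [t for t in table.columns if prevalence[t] >= min_prevalence]
    rel = rel[kept]

    graph = nx.Graph()
    graph.add_nodes_from(kept)
    rows = []
    if len(kept) >= 2:
        rho, pval = stats.spearmanr(rel.to_numpy())
        rho = np.atleast_2d(rho)
        pval = np.atleast_2d(pval)
        for i in range(len(kept)):
            for j in range(i + 1, len(kept)):
                r, p = float(rho[i, j]), float(pval[i, j])
                if np.isnan(r):
                    continue
                if abs(r) >= r_threshold and p <= p_threshold:
                    graph.add_edge(kept[i], kept[j], r=r, p=p,
                                   weight=abs(r), sign=int(np.sign(r)))
                    rows.append((kept[i], kept[j], r, p))
    edges = pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "r", "p"])
    return CooccurrenceNetwork(graph, edges, r_threshold, p_threshold)


@dataclass
class TopologyStats:
    n_nodes: int
    n_edges: int
    average_degree: float
    average_weighted_degree: float
    modularity: float
    mean_eigenvector_centrality: float
    no_edges: bool = False


def topology_stats(net: CooccurrenceNetwork, seed: int | None = 0) -> TopologyStats:
    """Degree means, greedy-modularity partition quality, and mean
    eigenvector centrality of the largest connected component.

    The greedy agglomerative community algorithm is deterministic, unlike
    Louvain, so repeated runs agree exactly.
    """
    g = net.graph
    n = g.number_of_nodes()
    if n == 0:
        raise DegenerateInputError("empty network")
    e = g.number_of_edges()
    if e == 0:
        return TopologyStats(n, 0, 0.0, 0.0, 0.0, 0.0, no_edges=True)
    avg_deg = 2.0 * e / n
    avg_wdeg = float(np.mean([d for _, d in g.degree(weight="weight")]))
    comms = nx.community.greedy_modularity_communities(g, weight="weight")
    mod = nx.community.modularity(g, comms, weight="weight")
    giant = sorted(max(nx.connected_components(g), key=len))
    adj = nx.to_numpy_array(g, nodelist=giant, weight="weight")
    # own power iteration: ARPACK-based alternatives start from a random
    # vector and break bit-level run-to-run reproducibility
    eig = _eigencentrality_power(adj)
    return TopologyStats(n, e, avg_deg, avg_wdeg, float(mod),
                         float(np.mean(eig)))


@dataclass
class KeystoneRanking:
    scores: pd.DataFrame        # node, pagerank, eigencentrality, combined_rank
    keystones: list[str]        # top_k of either score
    damping: float


def _pagerank_power(nodes, adj: np.ndarray, damping: float,
                    tol: float = 1e-10, max_iter: int = 10_000) -> np.ndarray:
    """PageRank by power iteration on a weighted undirected adjacency.

    Dangling (isolated) nodes redistribute their mass uniformly, so they
    end up with essentially teleport-only scores.
    """
    n = len(nodes)
    col_sums = adj.sum(axis=0)
    dangling = col_sums == 0
    M = np.where(col_sums > 0, adj / np.where(col_sums > 0, col_sums, 1.0), 0.0)
    p = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        new = damping * (M @ p + p[dangling].sum() / n) + (1 - damping) / n
        if np.abs(new - p).sum() < tol:
            return new
        p = new
    return p


def _eigencentrality_power(adj: np.ndarray, tol: float = 1e-10,
                           max_iter: int = 10_000) -> np.ndarray:
    v = np.full(adj.shape[0], 1.0)
    for _ in range(max_iter):
        new = adj @ v
        norm = np.linalg.norm(new)
        if norm == 0:
            return v
        new /= norm
        if np.abs(new - v).max() < tol:
            v = new
            break
        v = new
    return np.abs(v)


def keystone_rank(net: CooccurrenceNetwork, damping: float = 0.85,
                  top_k: int = 9) -> KeystoneRanking:
    """Rank taxa by PageRank and eigenvector centrality; top scorers of
    either measure are the keystones.

    PageRank (power iteration, tolerance 1e-10) runs on the full
    |r|-weighted graph and sums to 1; eigenvector centrality runs on the
    largest connected component (isolated nodes score 0) and is
    normalized so the maximum is exactly 1.  Ties break by node label
    order.
    """
    g = net.graph
    if g.number_of_edges() < 1:
        raise DegenerateInputError("keystone ranking needs >= 1 edge")
    nodes = sorted(g.nodes)
    adj = nx.to_numpy_array(g, nodelist=nodes, weight="weight")
    pr = _pagerank_power(nodes, adj, damping)
    pr /= pr.sum()

    giant = sorted(max(nx.connected_components(g), key=len))
    sub = nx.to_numpy_array(g, nodelist=giant, weight="weight")
    ev_giant = _eigencentrality_power(sub)
    ev_giant /= ev_giant.max()
    ev = pd.Series(0.0, index=nodes)
    ev[giant] = ev_giant

    scores = pd.DataFrame({
        "node": nodes,
        "pagerank": pr,
        "eigencentrality": ev.to_numpy(),
    })
    scores["pagerank_rank"] = scores["pagerank"].rank(
        ascending=False, method="first")
    scores["eigencentrality_rank"] = scores["eigencentrality"].rank(
        ascending=False, method="first")
    scores["combined_rank"] = scores[
        ["pagerank_rank", "eigencentrality_rank"]].min(axis=1)
    top_pr = scores.nsmallest(top_k, "pagerank_rank")["node"]
    top_ev = scores.nsmallest(top_k, "eigencentrality_rank")["node"]
    keystones = sorted(set(top_pr) | set(top_ev))
    return KeystoneRanking(scores, keystones, damping)
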