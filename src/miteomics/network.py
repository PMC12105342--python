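"""Gene co-expression graph construction and Markov clustering.

The graph is built from per-stage mean TPM vectors: genes are connected when
the Pearson correlation of their stage profiles reaches a cutoff (0.9 by
default). Clustering uses the Markov Cluster algorithm (MCL): a random walk
on the graph is alternately expanded (matrix squaring) and inflated
(elementwise power with column renormalization); the inflation exponent is
the granularity knob — higher inflation, finer clusters. Edge weights are
kept as matrix entries (weighted MCL) and self-loops are set to each node's
maximum incident edge weight. Clusters may afterwards be curated by merging
pairs whose centroid stage profiles are nearly collinear.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd


@dataclass
class ClusterAssignment:
    """A partition of graph nodes into clusters 1..K."""

    labels: pd.Series  # gene_id -> cluster id
    converged: bool = True
    n_iterations: int = 0
    centroids: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def n_clusters(self) -> int:
        return int(self.labels.nunique())

    def members(self, cluster_id: int) -> list:
        return list(self.labels.index[self.labels == cluster_id])


def build_graph(stage_mean_tpm: pd.DataFrame, r_min: float = 0.9) -> nx.Graph:
    """Correlation graph over per-stage mean expression vectors.

    An edge (g, h) carries weight r = Pearson correlation of the two genes'
    stage-mean vectors and is present iff r >= r_min. Genes constant across
    stages are excluded (their correlation is undefined). With only two
    stages every correlation is +/-1, which is degenerate; a warning is
    raised.
    """
    if stage_mean_tpm.shape[1] < 3:
        warnings.warn("fewer than 3 stage values: correlations are degenerate",
                      stacklevel=2)
    x = stage_mean_tpm.to_numpy(dtype=float)
    keep = x.std(axis=1) > 0
    genes = stage_mean_tpm.index[keep]
    g = nx.Graph()
    g.add_nodes_from(genes)
    if keep.sum() >= 2:
        r = np.corrcoef(x[keep])
        iu, ju = np.triu_indices(len(genes), k=1)
        hit = r[iu, ju] >= r_min
        g.add_weighted_edges_from(
            (genes[i], genes[j], float(r[i, j]))
            for i, j in zip(iu[hit], ju[hit]))
    return g


def _mcl_matrix(m: np.ndarray, inflation: float, prune: float,
                max_iter: int, tol: float) -> tuple[np.ndarray, bool, int]:
    """Iterate expansion/inflation on a column-stochastic matrix."""

    def normalize(a: np.ndarray) -> np.ndarray:
        colsum = a.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        return a / colsum

    m = normalize(m)
    for it in range(1, max_iter + 1):
        expanded = m @ m
        inflated = normalize(expanded ** inflation)
        inflated[inflated < prune] = 0.0
        inflated = normalize(inflated)
        delta = np.abs(inflated - m).max()
        m = inflated
        if delta < tol:
            return m, True, it
    return m, False, max_iter


def mcl(graph: nx.Graph, inflation: float = 3.0, prune: float = 1e-5,
        max_iter: int = 200, tol: float = 1e-8) -> ClusterAssignment:
    """Markov clustering of a weighted graph.

    Self-loops are added with each node's maximum incident edge weight
    (1.0 for isolated nodes) before column normalization. Clusters are read
    from the attractor rows of the converged matrix; a node attracted by
    several attractors is resolved to the lowest cluster id. Non-convergence
    within ``max_iter`` returns the current state flagged unconverged.
    """
    if inflation <= 1.0:
        raise ValueError("inflation must be > 1")
    nodes = list(graph.nodes)
    if not nodes:
        raise ValueError("graph is empty")
    a = nx.to_numpy_array(graph, nodelist=nodes, weight="weight")
    loop = a.max(axis=1)
    loop[loop <= 0] = 1.0
    np.fill_diagonal(a, loop)
    m, converged, n_iter = _mcl_matrix(a, inflation, prune, max_iter, tol)
    if not converged:
        warnings.warn(f"MCL did not converge in {max_iter} iterations",
                      stacklevel=2)

    attractors = np.where(np.diag(m) > prune)[0]
    labels = np.full(len(nodes), -1, dtype=int)
    next_id = 1
    for i in attractors:
        support = np.where(m[i] > prune)[0]
        unassigned = support[labels[support] == -1]
        if labels[i] != -1:
            cid = labels[i]  # attractor already claimed by a lower cluster
        else:
            cid = next_id
            next_id += 1
        labels[unassigned] = cid
    # stragglers (possible in unconverged states): follow the strongest row
    for j in np.where(labels == -1)[0]:
        i = int(np.argmax(m[:, j]))
        labels[j] = labels[i] if labels[i] != -1 else next_id
        if labels[j] == next_id:
            next_id += 1
    # renumber compactly in order of first appearance
    relabel: dict[int, int] = {}
    for v in labels:
        relabel.setdefault(int(v), len(relabel) + 1)
    series = pd.Series([relabel[int(v)] for v in labels],
                       index=pd.Index(nodes, name="gene_id"), name="cluster")
    return ClusterAssignment(series, converged=converged, n_iterations=n_iter)


def cluster_centroids(assignment: ClusterAssignment,
                      stage_mean_tpm: pd.DataFrame) -> pd.DataFrame:
    """Mean stage profile per cluster (clusters x stages)."""
    profiles = stage_mean_tpm.loc[assignment.labels.index]
    return profiles.groupby(assignment.labels).mean()


def curate_clusters(assignment: ClusterAssignment,
                    stage_mean_tpm: pd.DataFrame,
                    min_centroid_r: float = 0.95) -> ClusterAssignment:
    """Merge clusters with nearly identical centroid stage profiles.

    Repeatedly merges the pair of clusters with the highest centroid
    Pearson correlation while it exceeds ``min_centroid_r``; ties break on
    the lowest id pair and the merged cluster keeps the lower id. Constant
    centroids (zero variance) never merge (correlation undefined).
    """
    labels = assignment.labels.copy()
    while True:
        cents = stage_mean_tpm.loc[labels.index].groupby(labels).mean()
        ids = list(cents.index)
        if len(ids) < 2:
            break
        x = cents.to_numpy(dtype=float)
        sd = x.std(axis=1)
        best: tuple[float, int, int] | None = None
        for a in range(len(ids)):
            for b in range(a + 1, len(ids)):
                if sd[a] == 0 or sd[b] == 0:
                    continue
                r = float(np.corrcoef(x[a], x[b])[0, 1])
                if best is None or r > best[0] + 1e-12:
                    best = (r, ids[a], ids[b])
        if best is None or best[0] <= min_centroid_r:
            break
        _, keep, drop = best
        labels[labels == drop] = keep
    relabel: dict[int, int] = {}
    for v in labels:
        relabel.setdefault(int(v), len(relabel) + 1)
    curated = labels.map(relabel).rename("curated_cluster")
    cents = stage_mean_tpm.loc[curated.index].groupby(curated).mean()
    return ClusterAssignment(curated, converged=assignment.converged,
                             n_iterations=assignment.n_iterations,
                             centroids=cents)


def write_edge_list(graph: nx.Graph, path) -> None:
    rows = [(a, b, d["weight"]) for a, b, d in graph.edges(data=True)]
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "r"]).to_csv(
        path, sep="\t", index=False)


def write_clusters(assignment: ClusterAssignment,
                   curated: ClusterAssignment | None, path) -> None:
    df = assignment.labels.rename("cluster_id").to_frame()
    if curated is not None:
        df["curated_cluster_id"] = curated.labels
    df.to_csv(path, sep="\t", index_label="gene_id")
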