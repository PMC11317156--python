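"""Compositional ensemble association networks and consensus communities.

Relative-abundance (compositional) count tables cannot be correlated
naively; the pipeline here is the compositionally-valid route: centered
log-ratio (CLR) transform, partial correlations from a shrinkage
covariance estimate (Schafer-Strimmer: off-diagonal correlations shrunk
toward zero with an analytic intensity, i.e. covariance shrunk toward its
diagonal), bootstrap ensembling over samples (N_Draws = 100 by default),
subsetting the sign-stable positive associations, consensus Leiden
communities over many seeds (N_Seeds = 100), and weighted-degree
connectivity rankings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

try:  # igraph + leidenalg are required for community detection only
    import igraph as ig
    import leidenalg
except ImportError:  # pragma: no cover
    ig = None
    leidenalg = None


def clr_transform(counts: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Centered log-ratio transform per sample (row).

    Each row becomes log(x + pseudocount) minus the row mean of logs, so
    every output row sums to zero.  A positive pseudocount keeps zero
    counts finite.
    """
    if pseudocount <= 0:
        raise ValueError(f"pseudocount must be positive, got {pseudocount}")
    values = counts.to_numpy(dtype=float) + pseudocount
    if (values <= 0).any():
        raise ValueError("counts must be non-negative")
    logs = np.log(values)
    clr = logs - logs.mean(axis=1, keepdims=True)
    return pd.DataFrame(clr, index=counts.index, columns=counts.columns)


def shrinkage_covariance(X: np.ndarray) -> tuple[np.ndarray, float]:
    """Schafer-Strimmer shrinkage covariance with a diagonal target.

    Empirical correlations are shrunk toward zero with the analytic
    intensity lambda* = sum Var(r_ij) / sum r_ij^2 (clamped to [0, 1]);
    variances are kept, so the covariance is shrunk toward its diagonal.
    Returns the shrunk covariance and lambda.
    """
    n, p = X.shape
    if n < 3 or p < 2:
        raise ValueError(f"need >= 3 samples and >= 2 features, got {n} x {p}")
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValueError("constant feature: correlation undefined")
    Z = Xc / sd
    R = (Z.T @ Z) / (n - 1)
    # unbiased estimate of Var(r_ij) from the products of standardized scores
    W = Z[:, :, None] * Z[:, None, :]
    Wbar = W.mean(axis=0)
    var_r = n / (n - 1) ** 3 * ((W - Wbar) ** 2).sum(axis=0)
    off = ~np.eye(p, dtype=bool)
    denom = (R[off] ** 2).sum()
    lam = 1.0 if denom == 0 else float(np.clip(var_r[off].sum() / denom, 0.0, 1.0))
    R_shrunk = (1.0 - lam) * R
    np.fill_diagonal(R_shrunk, 1.0)
    return R_shrunk * np.outer(sd, sd), lam


def shrinkage_partial_correlation(clr_matrix: pd.DataFrame) -> pd.DataFrame:
    """Partial correlations from the shrunk covariance of CLR data.

    The shrunk covariance is inverted and the precision matrix P scaled to
    partial correlations pc(i, j) = -P_ij / sqrt(P_ii P_jj); the diagonal
    is set to 1.  Requires at least 3 samples and 3 features.
    """
    X = clr_matrix.to_numpy(dtype=float)
    n, p = X.shape
    if n < 3 or p < 3:
        raise ValueError(f"need >= 3 samples and >= 3 features, got {n} x {p}")
    cov, lam = shrinkage_covariance(X)
    try:
        precision = np.linalg.inv(cov)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "shrunk covariance is singular (lambda = "
            f"{lam:.3g}); consider a larger pseudocount or more samples"
        ) from err
    d = np.sqrt(np.diag(precision))
    pcor = -precision / np.outer(d, d)
    np.fill_diagonal(pcor, 1.0)
    pcor = np.clip(pcor, -1.0, 1.0)
    return pd.DataFrame(pcor, index=clr_matrix.columns, columns=clr_matrix.columns)


@dataclass
class EnsembleNetwork:
    """Bootstrap-averaged association network over composition features."""

    nodes: list[str]
    mean_weight: pd.DataFrame  # symmetric, unit diagonal ignored
    support: pd.DataFrame  # fraction of draws with positive weight
    n_draws: int
    seed: int

    def edges(self) -> list[tuple[str, str, float, float]]:
        out = []
        for i, a in enumerate(self.nodes):
            for b in self.nodes[i + 1 :]:
                out.append(
                    (a, b, float(self.mean_weight.loc[a, b]), float(self.support.loc[a, b]))
                )
        return out


def ensemble_network(
    counts: pd.DataFrame,
    n_draws: int = 100,
    seed: int = 0,
    pseudocount: float = 1.0,
) -> EnsembleNetwork:
    """Bootstrap ensemble of CLR shrinkage partial-correlation networks.

    For each draw, samples (rows) are resampled with replacement,
    CLR-transformed, and the shrinkage partial-correlation matrix computed.
    Edge mean weights average the draws; support is the fraction of draws
    in which the edge weight was strictly positive.  Deterministic given
    ``seed``.
    """
    if n_draws < 1:
        raise ValueError(f"n_draws must be >= 1, got {n_draws}")
    n = counts.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 samples, got {n}")
    rng = np.random.default_rng(seed)
    nodes = list(counts.columns)
    acc = np.zeros((len(nodes), len(nodes)))
    pos = np.zeros((len(nodes), len(nodes)))
    for _ in range(n_draws):
        idx = rng.integers(0, n, n)
        draw = counts.iloc[idx]
        pcor = shrinkage_partial_correlation(
            clr_transform(draw, pseudocount)
        ).to_numpy()
        acc += pcor
        pos += pcor > 0
    mean = pd.DataFrame(acc / n_draws, index=nodes, columns=nodes)
    support = pd.DataFrame(pos / n_draws, index=nodes, columns=nodes)
    return EnsembleNetwork(
        nodes=nodes, mean_weight=mean, support=support, n_draws=n_draws, seed=seed
    )


def positive_subgraph(
    network: EnsembleNetwork, min_support: float = 0.5
) -> nx.Graph:
    """Graph of positive associations: mean weight > 0 and support >= min.

    The strict inequality on the mean weight excludes exactly-zero edges;
    the support threshold suppresses sign-unstable edges.
    """
    graph = nx.Graph()
    graph.add_nodes_from(network.nodes)
    for a, b, weight, support in network.edges():
        if weight > 0 and support >= min_support:
            graph.add_edge(a, b, weight=weight, support=support)
    return graph


@dataclass
class ConsensusCommunities:
    membership: dict[str, int]  # community ids contiguous from 1
    co_membership: pd.DataFrame  # fraction of seeds co-assigned
    n_seeds: int


def _adjusted_rand(labels_a: list[int], labels_b: list[int]) -> float:
    from sklearn.metrics import adjusted_rand_score

    return float(adjusted_rand_score(labels_a, labels_b))


def consensus_communities(
    graph: nx.Graph,
    n_seeds: int = 100,
    base_seed: int = 0,
    resolution: float = 1.0,
) -> ConsensusCommunities:
    """Consensus Leiden communities over many seeded runs.

    Leiden (RB-configuration modularity, weighted) runs once per seed; the
    consensus partition is the medoid run — the one with maximal mean
    adjusted Rand agreement with all other runs — which is always a valid
    partition.  Community ids are renumbered 1..C by decreasing size, ties
    broken by smallest member node.  Deterministic given ``base_seed``.
    """
    if leidenalg is None or ig is None:  # pragma: no cover
        raise ImportError("consensus_communities requires python-igraph and leidenalg")
    nodes = sorted(graph.nodes)
    if not nodes:
        return ConsensusCommunities({}, pd.DataFrame(), n_seeds)
    index = {node: i for i, node in enumerate(nodes)}
    edges = [(index[a], index[b]) for a, b in graph.edges]
    weights = [float(graph.edges[a, b].get("weight", 1.0)) for a, b in graph.edges]
    if any(w < 0 for w in weights):
        raise ValueError("graph weights must be non-negative")
    g = ig.Graph(n=len(nodes), edges=edges)

    runs: list[list[int]] = []
    co = np.zeros((len(nodes), len(nodes)))
    for s in range(n_seeds):
        partition = leidenalg.find_partition(
            g,
            leidenalg.RBConfigurationVertexPartition,
            weights=weights or None,
            resolution_parameter=resolution,
            seed=base_seed + s,
        )
        labels = list(partition.membership)
        runs.append(labels)
        arr = np.asarray(labels)
        co += arr[:, None] == arr[None, :]
    co /= n_seeds

    if n_seeds == 1:
        medoid = runs[0]
    else:
        scores = [
            np.mean([_adjusted_rand(run, other) for other in runs if other is not run])
            for run in runs
        ]
        medoid = runs[int(np.argmax(scores))]

    groups: dict[int, list[str]] = {}
    for node, label in zip(nodes, medoid):
        groups.setdefault(label, []).append(node)
    ordered = sorted(groups.values(), key=lambda members: (-len(members), members[0]))
    membership = {
        node: community_id
        for community_id, members in enumerate(ordered, start=1)
        for node in members
    }
    co_membership = pd.DataFrame(co, index=nodes, columns=nodes)
    return ConsensusCommunities(
        membership=membership, co_membership=co_membership, n_seeds=n_seeds
    )


def weighted_degree_ranking(graph: nx.Graph) -> list[tuple[str, float]]:
    """Nodes ranked by the sum of incident positive edge weights.

    Descending by weighted degree, ties broken lexicographically; isolated
    nodes rank last with degree 0.
    """
    degrees = {
        node: sum(
            data.get("weight", 1.0)
            for _, _, data in graph.edges(node, data=True)
            if data.get("weight", 1.0) > 0
        )
        for node in graph.nodes
    }
    return sorted(degrees.items(), key=lambda kv: (-kv[1], kv[0]))


def to_node_link_json(graph: nx.Graph) -> dict:
    """JSON-serializable node-link representation of a graph."""
    return nx.node_link_data(graph, edges="links")
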