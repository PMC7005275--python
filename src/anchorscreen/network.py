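"""Hit networks from co-essentiality correlations or combined-score edges.

Screen hits (|average Z| above a threshold, default 2) become nodes; edges
come from an external association source — a gene-by-gene Pearson
correlation matrix of fitness profiles (edge iff |r| > cutoff, weight |r|)
or a scored pair list on a 0–1000 scale normalized to [0, 1] (edge iff
score > cutoff, weight score).  Communities are found by Louvain-style
weighted modularity optimization, and the observed edge count is compared
with random gene sets of the same order drawn from a declared universe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CORRELATION_CUTOFF = 0.2   # |Pearson r| for co-essentiality edges
STRING_CUTOFF = 0.4        # combined score (0-1 scale; 400 on the 0-1000 scale)
HIT_Z_THRESHOLD = 2.0


def select_hit_nodes(
    combined_scores: pd.DataFrame, threshold: float = HIT_Z_THRESHOLD
) -> list[str]:
    """Genes with |average Z| strictly greater than the threshold."""
    hits = combined_scores.index[combined_scores["avg_z"].abs() > threshold]
    if len(hits) == 0:
        logger.warning("no genes exceed |avg_z| > %g", threshold)
    return list(hits)


def read_correlation_matrix(path: str | Path) -> pd.DataFrame:
    mat = pd.read_csv(path, sep="\t", index_col=0)
    validate_correlations(mat)
    return mat


def validate_correlations(mat: pd.DataFrame) -> None:
    vals = mat.to_numpy(dtype=float)
    if mat.shape[0] != mat.shape[1] or list(mat.index) != list(mat.columns):
        raise ValueError("correlation matrix must be square with matching labels")
    if not np.allclose(vals, vals.T, atol=1e-12):
        raise ValueError("correlation matrix is not symmetric")
    if np.any(np.abs(vals) > 1 + 1e-12):
        raise ValueError("correlations outside [-1, 1]")
    if not np.allclose(np.diag(vals), 1.0):
        raise ValueError("correlation matrix diagonal is not 1")


def read_scored_edges(path: str | Path, scale: float = 1000.0) -> pd.DataFrame:
    """Scored pair list (geneA, geneB, combined_score on 0–1000), normalized
    to [0, 1]; unordered duplicates collapse to their maximum score."""
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    df.columns = ["gene_a", "gene_b", "score"][: len(df.columns)]
    df["score"] = df["score"].astype(float) / scale
    if ((df["score"] < 0) | (df["score"] > 1)).any():
        raise ValueError("combined scores outside the 0-1000 input scale")
    ordered = df["gene_a"] <= df["gene_b"]
    a = df["gene_a"].where(ordered, df["gene_b"])
    b = df["gene_b"].where(ordered, df["gene_a"])
    out = (
        pd.DataFrame({"gene_a": a, "gene_b": b, "score": df["score"]})
        .groupby(["gene_a", "gene_b"], as_index=False)["score"]
        .max()
    )
    return out[out["gene_a"] != out["gene_b"]]


def build_network(
    genes: Sequence[str],
    edges: pd.DataFrame,
    cutoff: float,
    mode: str = "corr",
    node_weights: pd.Series | None = None,
) -> nx.Graph:
    """Threshold an edge source into a weighted hit network.

    ``mode='corr'``: ``edges`` is a square correlation matrix; edge iff
    |r| > cutoff with weight |r|.  ``mode='string'``: ``edges`` is a scored
    pair frame (gene_a, gene_b, score in [0,1]); edge iff score > cutoff.
    Genes absent from the edge source stay as isolated nodes.
    """
    if not 0 < cutoff < 1:
        raise ValueError("cutoff must be in (0, 1)")
    graph = nx.Graph()
    for g in genes:
        weight = float(node_weights.get(g, np.nan)) if node_weights is not None else np.nan
        graph.add_node(g, avg_z=weight, size=abs(weight) if np.isfinite(weight) else 0.0)

    gene_list = list(genes)
    if mode == "corr":
        known = [g for g in gene_list if g in edges.index]
        missing = set(gene_list) - set(known)
        if missing:
            logger.info("%d genes absent from the correlation matrix", len(missing))
        sub = edges.loc[known, known].to_numpy(dtype=float)
        for i in range(len(known)):
            for j in range(i + 1, len(known)):
                r = sub[i, j]
                if abs(r) > cutoff:
                    graph.add_edge(known[i], known[j], weight=abs(r))
    elif mode == "string":
        gene_set = set(gene_list)
        covered = set(edges["gene_a"]) | set(edges["gene_b"])
        missing = gene_set - covered
        if missing:
            logger.info("%d genes absent from the scored edge list", len(missing))
        for row in edges.itertuples(index=False):
            if row.gene_a in gene_set and row.gene_b in gene_set and row.score > cutoff:
                graph.add_edge(row.gene_a, row.gene_b, weight=float(row.score))
    else:
        raise ValueError(f"unknown mode {mode!r}; expected 'corr' or 'string'")
    return graph


@dataclass(frozen=True)
class ClusterAssignment:
    clusters: dict[str, int]
    modularity: float


def _partition_modularity(adj: np.ndarray, labels: np.ndarray) -> float:
    """Weighted modularity of a labelling over a dense adjacency matrix."""
    total = adj.sum()
    deg = adj.sum(axis=1)
    q = 0.0
    for c in np.unique(labels):
        idx = labels == c
        q += adj[np.ix_(idx, idx)].sum() / total - (deg[idx].sum() / total) ** 2
    return float(q)


def _kl_refine(adj: np.ndarray, labels: np.ndarray, max_sweeps: int = 50) -> tuple[np.ndarray, float]:
    """Kernighan–Lin-style modularity polish of a partition.

    Each sweep applies the globally best single-node move (to any community,
    or a fresh singleton) even when its gain is negative, locks the moved
    node, and finally rewinds to the best partition seen along the trail.
    Sweeps repeat while they improve.  This escapes the local optima that
    single-move hill climbing (and Louvain's aggregation) cannot leave.
    """
    n = len(labels)
    total = adj.sum()
    deg = adj.sum(axis=1)
    best_labels = _compress_labels(labels)
    best_mod = _partition_modularity(adj, best_labels)
    for _ in range(max_sweeps):
        cur = best_labels.copy()
        cur_mod = best_mod
        n_comms = int(cur.max()) + 1
        # node-to-community edge weights and community degree totals,
        # with one spare column standing for "a new singleton community"
        comm_w = np.zeros((n, n_comms + 1))
        comm_deg = np.zeros(n_comms + 1)
        for c in range(n_comms):
            members = cur == c
            comm_w[:, c] = adj[:, members].sum(axis=1)
            comm_deg[c] = deg[members].sum()
        locked = np.zeros(n, dtype=bool)
        improved = False
        for _step in range(n):
            own_w = comm_w[np.arange(n), cur]
            own_deg = comm_deg[cur]
            # gain of moving each node to each community (vectorized)
            gains = (
                2.0 * (comm_w - own_w[:, None]) / total
                - 2.0 * deg[:, None] * (comm_deg[None, :] - own_deg[:, None] + deg[:, None]) / total**2
            )
            gains[np.arange(n), cur] = -np.inf
            gains[locked, :] = -np.inf
            flat = int(np.argmax(gains))
            v, target = divmod(flat, n_comms + 1)
            if not np.isfinite(gains[v, target]):
                break
            source = cur[v]
            cur_mod += gains[v, target]
            cur[v] = target
            locked[v] = True
            comm_w[:, source] -= adj[:, v]
            comm_w[:, target] += adj[:, v]
            comm_deg[source] -= deg[v]
            comm_deg[target] += deg[v]
            if target == n_comms:  # opened the spare column; add a new one
                comm_w = np.column_stack([comm_w, np.zeros(n)])
                comm_deg = np.append(comm_deg, 0.0)
                n_comms += 1
            if cur_mod > best_mod + 1e-12:
                best_mod = cur_mod
                best_labels = cur.copy()
                improved = True
        if not improved:
            break
    best_labels = _compress_labels(best_labels)
    return best_labels, _partition_modularity(adj, best_labels)


def _compress_labels(labels: np.ndarray) -> np.ndarray:
    _, out = np.unique(labels, return_inverse=True)
    return out.astype(int)


def cluster_modularity(
    net: nx.Graph,
    seed: int = 0,
    n_restarts: int = 4,
    n_random_starts: int = 8,
) -> ClusterAssignment:
    """Weighted-modularity communities, deterministic given seed.

    Louvain-style greedy optimization with two robustness layers: the
    Louvain pass is restarted ``n_restarts`` times with sub-seeds derived
    from ``seed``, ``n_random_starts`` additional searches begin from random
    partitions, and every candidate is polished by a Kernighan–Lin move
    sweep (see ``_kl_refine``).  The highest-modularity partition wins.
    Nodes are relabelled into sorted order first, so the result depends only
    on the graph and the seed.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("cannot cluster an empty network")
    nodes = sorted(net.nodes)
    relabel = {g: i for i, g in enumerate(nodes)}
    n = len(nodes)
    if net.number_of_edges() == 0:
        return ClusterAssignment(
            clusters={g: i for i, g in enumerate(nodes)}, modularity=0.0
        )
    canonical = nx.relabel_nodes(net, relabel, copy=True)
    adj = np.zeros((n, n))
    for u, v, d in canonical.edges(data=True):
        w = float(d.get("weight", 1.0))
        adj[u, v] = adj[v, u] = w

    seed_seq = np.random.SeedSequence(seed).spawn(n_restarts + 1)
    starts: list[np.ndarray] = []
    for sub in seed_seq[:n_restarts]:
        comms = nx.community.louvain_communities(
            canonical, weight="weight", seed=int(sub.generate_state(1)[0] % (2**31))
        )
        labels = np.empty(n, dtype=int)
        for cid, members in enumerate(comms):
            labels[list(members)] = cid
        starts.append(labels)
    rng = np.random.default_rng(seed_seq[-1])
    for _ in range(n_random_starts):
        k = int(rng.integers(1, n + 1))
        starts.append(rng.integers(0, k, size=n))

    best_labels, best_mod = None, -np.inf
    for labels in starts:
        cand_labels, cand_mod = _kl_refine(adj, labels)
        if cand_mod > best_mod:
            best_labels, best_mod = cand_labels, cand_mod

    # stable cluster ids: order by smallest member node
    order = {}
    for cid in range(int(best_labels.max()) + 1):
        order[cid] = min(i for i in range(n) if best_labels[i] == cid)
    remap = {cid: rank for rank, (cid, _) in enumerate(sorted(order.items(), key=lambda kv: kv[1]))}
    clusters = {nodes[i]: remap[int(best_labels[i])] for i in range(n)}
    return ClusterAssignment(clusters=clusters, modularity=float(best_mod))


@dataclass(frozen=True)
class EdgeEnrichmentResult:
    observed_edges: int
    null_mean: float
    null_sd: float
    empirical_p: float
    n_random: int
    seed: int


def _count_edges(genes: Sequence[str], edges: pd.DataFrame, cutoff: float, mode: str) -> int:
    return build_network(genes, edges, cutoff, mode=mode).number_of_edges()


def edge_enrichment(
    hit_genes: Sequence[str],
    universe: Sequence[str],
    edges: pd.DataFrame,
    cutoff: float,
    mode: str = "corr",
    n_random: int = 1000,
    seed: int = 0,
) -> EdgeEnrichmentResult:
    """Edge-count enrichment of the hit network over random gene sets.

    Draws ``n_random`` uniform subsets of the universe with the same number
    of genes as the hit set, counts edges under the same cutoff, and reports
    the add-one empirical p-value (1 + #{null >= observed}) / (1 + n_random).
    """
    hit_genes = list(hit_genes)
    universe = list(universe)
    if len(universe) < len(hit_genes):
        raise ValueError("universe smaller than the hit set")
    observed = _count_edges(hit_genes, edges, cutoff, mode)
    rng = np.random.default_rng(seed)
    null = np.empty(n_random, dtype=np.int64)
    for i in range(n_random):
        draw = rng.choice(len(universe), size=len(hit_genes), replace=False)
        null[i] = _count_edges([universe[j] for j in draw], edges, cutoff, mode)
    p = (1 + int(np.sum(null >= observed))) / (1 + n_random)
    return EdgeEnrichmentResult(
        observed_edges=observed,
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=1)) if n_random > 1 else 0.0,
        empirical_p=float(p),
        n_random=n_random,
        seed=seed,
    )


def write_network(net: nx.Graph, clusters: ClusterAssignment | None, out_prefix: str | Path) -> None:
    """Export edge list TSV, cluster TSV, and GraphML."""
    out_prefix = Path(out_prefix)
    edges = pd.DataFrame(
        [(a, b, d.get("weight", 1.0)) for a, b, d in net.edges(data=True)],
        columns=["gene_a", "gene_b", "weight"],
    )
    edges.to_csv(out_prefix.with_suffix(".edges.tsv"), sep="\t", index=False)
    if clusters is not None:
        pd.DataFrame(
            {"gene_symbol": list(clusters.clusters), "cluster": list(clusters.clusters.values())}
        ).to_csv(out_prefix.with_suffix(".clusters.tsv"), sep="\t", index=False)
    nx.write_graphml(net, out_prefix.with_suffix(".graphml"))
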