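"""Spearman co-occurrence networks and per-sample subnetwork topology.

One whole network is built per depth per subcommunity from relative
abundances across all samples: nodes are taxa that are shared among the
three disturbance periods and reach a mean relative abundance of at
least 0.05%; edges connect taxa with |Spearman rho| >= 0.8 and
Benjamini-Hochberg adjusted p < 0.01.  The period signal is carried by
per-sample induced subgraphs (nodes with non-zero count in that sample),
whose topological properties — node and edge counts, average path
length, betweenness centralization, density, modularity — are compared
across periods with Kruskal-Wallis tests.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .community import CommunityTable, compare_groups_kw

RHO_THRESHOLD = 0.8
FDR_THRESHOLD = 0.01
NODE_MIN_REL_ABUND = 0.0005  # 0.05%

METRIC_NAMES = (
    "node_count",
    "edge_count",
    "average_path_length",
    "betweenness_centralization",
    "density",
    "modularity",
)


@dataclass
class CooccurrenceNetwork:
    """Thresholded Spearman graph plus its construction metadata."""

    graph: nx.Graph
    rho_threshold: float = RHO_THRESHOLD
    fdr_threshold: float = FDR_THRESHOLD
    metadata: dict = field(default_factory=dict)

    @property
    def nodes(self) -> list:
        return list(self.graph.nodes)


def network_node_filter(
    table: CommunityTable,
    periods,
    min_rel_abund: float = NODE_MIN_REL_ABUND,
) -> list:
    """Taxa shared among all three periods with mean abundance >= cut-off.

    A taxon is shared when it has a non-zero count in at least one
    sample of each period; the abundance filter uses the overall mean of
    per-sample relative abundances (inclusive >=).
    """
    periods = np.asarray(periods)
    if set(np.unique(periods)) != {"before", "mixing", "after"}:
        raise ValueError("all three periods must be present")
    rel = table.relative_abundance()
    present = table.counts > 0
    shared = pd.Series(True, index=table.taxa)
    for p in ("before", "mixing", "after"):
        shared &= present.loc[periods == p].any(axis=0)
    abundant = rel.mean(axis=0) >= min_rel_abund
    keep = table.taxa[(shared & abundant)].tolist()
    if not keep:
        warnings.warn("node filter removed every taxon", stacklevel=2)
    return keep


def _spearman_edges(rel: pd.DataFrame) -> pd.DataFrame:
    """All-pairs Spearman rho with two-sided t-approximation p-values."""
    taxa = list(rel.columns)
    x = rel.to_numpy()
    n = x.shape[0]
    constant = x.std(axis=0) == 0
    if constant.any():
        warnings.warn(
            f"constant taxa have undefined correlations: "
            f"{[t for t, c in zip(taxa, constant) if c]}",
            stacklevel=3,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho, p = stats.spearmanr(x)
    if np.isscalar(rho):  # two taxa
        rho = np.array([[1.0, rho], [rho, 1.0]])
        p = np.array([[0.0, p], [p, 0.0]])
    ii, jj = np.triu_indices(len(taxa), k=1)
    return pd.DataFrame(
        {
            "taxon1": [taxa[i] for i in ii],
            "taxon2": [taxa[j] for j in jj],
            "rho": rho[ii, jj],
            "p": p[ii, jj],
        }
    )


def build_network(
    table: CommunityTable,
    rho_threshold: float = RHO_THRESHOLD,
    fdr_threshold: float = FDR_THRESHOLD,
) -> CooccurrenceNetwork:
    """Whole co-occurrence network from a node-filtered table.

    All pairwise Spearman correlations (mid-rank ties) are computed on
    relative abundances; p-values are Benjamini-Hochberg adjusted across
    all pairs; an edge requires |rho| >= ``rho_threshold`` AND adjusted
    p < ``fdr_threshold``.  Constant taxa stay as isolated nodes.
    """
    if len(table.samples) < 5:
        raise ValueError("need at least 5 samples to estimate correlations")
    rel = table.relative_abundance()
    g = nx.Graph()
    g.add_nodes_from(table.taxa)
    edges = _spearman_edges(rel)
    valid = edges["p"].notna() & edges["rho"].notna()
    edges = edges.loc[valid].copy()
    if len(edges):
        edges["p_adj"] = multipletests(edges["p"], method="fdr_bh")[1]
        keep = (edges["rho"].abs() >= rho_threshold) & (edges["p_adj"] < fdr_threshold)
        for _, row in edges.loc[keep].iterrows():
            g.add_edge(
                row["taxon1"], row["taxon2"], rho=float(row["rho"]), p_adj=float(row["p_adj"])
            )
    meta = {
        "n_samples": int(len(table.samples)),
        "rho_threshold": rho_threshold,
        "fdr_threshold": fdr_threshold,
    }
    return CooccurrenceNetwork(g, rho_threshold, fdr_threshold, meta)


def sample_subnetwork(net: CooccurrenceNetwork, sample_counts: pd.Series) -> nx.Graph:
    """Induced subgraph on the taxa present (count > 0) in one sample."""
    present = [t for t in net.graph.nodes if sample_counts.get(t, 0) > 0]
    return net.graph.subgraph(present).copy()


def _betweenness_centralization(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    b = nx.betweenness_centrality(g, normalized=False)
    bmax = max(b.values())
    denom = (n - 1) ** 2 * (n - 2) / 2
    return sum(bmax - v for v in b.values()) / denom


def _greedy_modularity(g: nx.Graph) -> float:
    """Modularity of the deterministic greedy agglomerative partition."""
    comms = nx.community.greedy_modularity_communities(g)
    return nx.community.modularity(g, comms)


def topological_metrics(g: nx.Graph) -> dict:
    """Six topological properties of a simple undirected graph.

    * average_path_length: mean shortest-path length over *connected*
      node pairs only (NaN when no pair is connected);
    * betweenness_centralization: Freeman centralization of raw
      betweenness, 1 for a star (NaN for n < 3);
    * density: 2E / (N(N-1)) (NaN for n < 2);
    * modularity: deterministic greedy (CNM) partition, unweighted
      (NaN for edgeless graphs).
    """
    n = g.number_of_nodes()
    e = g.number_of_edges()
    out = {"node_count": n, "edge_count": e}
    # average path length over connected pairs
    total, pairs = 0, 0
    for _, lengths in nx.all_pairs_shortest_path_length(g):
        for d in lengths.values():
            if d > 0:
                total += d
                pairs += 1
    out["average_path_length"] = total / pairs if pairs else math.nan
    out["betweenness_centralization"] = (
        _betweenness_centralization(g) if n >= 3 else math.nan
    )
    out["density"] = 2 * e / (n * (n - 1)) if n >= 2 else math.nan
    out["modularity"] = _greedy_modularity(g) if e > 0 else math.nan
    return out


def subnetwork_metrics(
    net: CooccurrenceNetwork, table: CommunityTable
) -> pd.DataFrame:
    """Topological metrics of every sample's induced subnetwork."""
    rows = {}
    for s in table.samples:
        rows[s] = topological_metrics(sample_subnetwork(net, table.counts.loc[s]))
    return pd.DataFrame.from_dict(rows, orient="index").loc[table.samples]


def compare_metrics_by_period(
    metrics: pd.DataFrame, periods, alpha: float = 0.05
) -> dict:
    """Kruskal-Wallis (+ letters) of each topological metric across periods.

    Samples with an undefined (NaN) value of a metric are excluded from
    that metric's comparison.
    """
    periods = np.asarray(periods)
    out = {}
    for col in metrics.columns:
        vals = metrics[col].to_numpy(dtype=float)
        ok = np.isfinite(vals)
        try:
            out[col] = compare_groups_kw(vals[ok], periods[ok], alpha=alpha)
        except ValueError:
            out[col] = None  # too few usable samples in some period
    return out


# -- independent-check helpers ---------------------------------------------


def exhaustive_best_modularity(g: nx.Graph) -> tuple[float, list[set]]:
    """Best-partition modularity by exhaustive search (tiny graphs only).

    Enumerates all set partitions of the nodes; usable as an oracle for
    the greedy algorithm on graphs of <= ~8 nodes.
    """
    nodes = list(g.nodes)
    if len(nodes) > 10:
        raise ValueError("exhaustive search is limited to small graphs")

    def partitions(seq):
        if not seq:
            yield []
            return
        first, rest = seq[0], seq[1:]
        for smaller in partitions(rest):
            for i, block in enumerate(smaller):
                yield smaller[:i] + [block | {first}] + smaller[i + 1 :]
            yield [{first}] + smaller

    best_q, best_p = -math.inf, None
    for part in partitions(nodes):
        q = nx.community.modularity(g, part)
        if q > best_q:
            best_q, best_p = q, part
    return best_q, best_p
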