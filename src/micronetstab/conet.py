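"""Signed co-occurrence networks from abundance tables.

Edges are robust Spearman correlations: |rho| above a threshold (0.8 by
default) with a Benjamini-Hochberg adjusted p-value below alpha (0.05),
adjusted jointly over all tested taxon pairs. Topology metrics follow the
usual unweighted-simple-graph conventions; the correlation sign and strength
ride along as edge attributes only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tabio import AsvTable, DataValidationError


def filter_taxa(
    table: AsvTable,
    min_prevalence: float = 0.0,
    min_mean_relabund: float = 0.0,
) -> AsvTable:
    """Drop rare taxa before correlation testing.

    Retains taxa present (count > 0) in at least ``min_prevalence`` of
    samples and with mean relative abundance at least ``min_mean_relabund``.
    Zero-variance taxa are always dropped — Spearman is undefined for them.
    """
    counts = table.counts
    n_samples = counts.shape[1]
    prevalence = (counts > 0).sum(axis=1) / n_samples
    mean_rel = table.relative_abundance().mean(axis=1)
    variance = counts.var(axis=1)
    keep = (prevalence >= min_prevalence) & (mean_rel >= min_mean_relabund) & (variance > 0)
    if not keep.any():
        raise DataValidationError("taxon filter removed every taxon")
    return AsvTable(counts.loc[keep])


@dataclass(frozen=True)
class CorrelationResult:
    """All-pairs Spearman correlations with raw and BH-adjusted p-values."""

    rho: pd.DataFrame
    p_raw: pd.DataFrame
    p_adj: pd.DataFrame
    n_pairs_tested: int


def spearman_matrix(table: AsvTable, force: bool = False) -> CorrelationResult:
    """Spearman rho (mid-rank Pearson) between all taxon pairs, with
    two-sided p-values from the t approximation and a single BH adjustment
    across the whole upper triangle."""
    n_samples = table.shape[1]
    if n_samples < 4 and not force:
        raise DataValidationError(
            f"Spearman p-values unreliable with {n_samples} samples (<4); "
            "pass force=True to override"
        )
    variances = table.counts.var(axis=1)
    flat = variances.index[variances == 0].tolist()
    if flat:
        raise DataValidationError(
            f"zero-variance taxa (filter first): {flat[:5]}"
        )
    X = table.counts.to_numpy().T.astype(float)  # samples x taxa
    rho, p = stats.spearmanr(X)
    if np.ndim(rho) == 0:  # scipy collapses the 2-taxon case to scalars
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
        p = np.array([[0.0, float(p)], [float(p), 0.0]])
    taxa = table.taxon_ids
    iu = np.triu_indices(len(taxa), k=1)
    p_flat = p[iu]
    p_adj_flat = multipletests(p_flat, method="fdr_bh")[1]
    p_adj = np.ones_like(p)
    p_adj[iu] = p_adj_flat
    p_adj[(iu[1], iu[0])] = p_adj_flat
    np.fill_diagonal(p_adj, 0.0)
    return CorrelationResult(
        rho=pd.DataFrame(rho, index=taxa, columns=taxa),
        p_raw=pd.DataFrame(p, index=taxa, columns=taxa),
        p_adj=pd.DataFrame(p_adj, index=taxa, columns=taxa),
        n_pairs_tested=len(p_flat),
    )


@dataclass(frozen=True)
class CoNetwork:
    """Signed undirected co-occurrence network plus its construction
    parameters; nodes are taxa with at least one retained edge."""

    graph: nx.Graph
    rho_min: float
    alpha: float

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def build_network(
    corr: CorrelationResult,
    rho_min: float = 0.8,
    alpha: float = 0.05,
    abundances: pd.Series | None = None,
) -> CoNetwork:
    """Threshold a correlation matrix into a signed network.

    An edge exists iff |rho| > rho_min (strict) and p_adj < alpha (strict).
    Isolated taxa are excluded; an empty edge set yields an empty network,
    not an error.
    """
    rho = corr.rho.to_numpy()
    p_adj = corr.p_adj.to_numpy()
    taxa = list(corr.rho.index)
    g = nx.Graph()
    iu = np.triu_indices(len(taxa), k=1)
    mask = (np.abs(rho[iu]) > rho_min) & (p_adj[iu] < alpha)
    for i, j in zip(iu[0][mask], iu[1][mask]):
        r = float(rho[i, j])
        g.add_edge(
            taxa[i],
            taxa[j],
            rho=r,
            p_adj=float(p_adj[i, j]),
            sign="+" if r > 0 else "-",
        )
    if abundances is not None:
        for node in g.nodes:
            g.nodes[node]["mean_relabund"] = float(abundances.get(node, np.nan))
    return CoNetwork(graph=g, rho_min=rho_min, alpha=alpha)


@dataclass(frozen=True)
class TopologyMetrics:
    n_nodes: int
    n_edges: int
    n_positive_edges: int
    n_negative_edges: int
    average_degree: float
    density: float
    clustering_coefficient: float
    average_path_length: float
    diameter: float
    n_components: int
    modularity: float
    n_modules: int
    # diagnostic rescalings: some published tables print path length and
    # diameter on a per-node scale
    average_path_length_per_node: float
    diameter_per_node: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def average_degree(n_nodes: int, n_edges: int) -> float:
    """Mean degree of a simple undirected graph, 2E/N."""
    if n_nodes == 0:
        raise ValueError("empty graph")
    return 2.0 * n_edges / n_nodes


def density(n_nodes: int, n_edges: int) -> float:
    """Edge density of a simple undirected graph, 2E/(N(N-1))."""
    if n_nodes < 2:
        raise ValueError("density needs at least 2 nodes")
    return 2.0 * n_edges / (n_nodes * (n_nodes - 1))


def percent_reduction(reference: float, value: float) -> float:
    """Relative decrease of ``value`` vs ``reference`` as a percentage."""
    return 100.0 * (reference - value) / reference


def louvain_partition(
    graph: nx.Graph, seed: int = 0, n_restarts: int = 10, resolution: float = 1.0
) -> tuple[list[set], float]:
    """Best-of-``n_restarts`` Louvain partition (deterministic given seed)
    and its Newman modularity."""
    best_q, best_part = -np.inf, None
    for r in range(n_restarts):
        part = nx.community.louvain_communities(
            graph, seed=seed + r, resolution=resolution
        )
        q = nx.community.modularity(graph, part, resolution=resolution)
        if q > best_q:
            best_q, best_part = q, part
    return best_part, float(best_q)


def topology(net: CoNetwork, community_seed: int = 0, n_restarts: int = 10) -> TopologyMetrics:
    """Topology metrics of the unweighted simple graph.

    Average path length and diameter are computed on the largest connected
    component (hop counts); the component count is reported alongside.
    Modularity is the Newman Q of the best seeded Louvain partition.
    """
    g = net.graph
    n, e = g.number_of_nodes(), g.number_of_edges()
    if n == 0:
        raise DataValidationError("empty network")
    n_pos = sum(1 for _, _, d in g.edges(data=True) if d.get("sign", "+") == "+")
    n_neg = e - n_pos
    components = list(nx.connected_components(g))
    giant = g.subgraph(max(components, key=len))
    if giant.number_of_nodes() > 1:
        apl = nx.average_shortest_path_length(giant)
        diam = float(nx.diameter(giant))
    else:
        apl, diam = 0.0, 0.0
    part, q = louvain_partition(g, seed=community_seed, n_restarts=n_restarts)
    return TopologyMetrics(
        n_nodes=n,
        n_edges=e,
        n_positive_edges=n_pos,
        n_negative_edges=n_neg,
        average_degree=average_degree(n, e),
        density=density(n, e) if n > 1 else 0.0,
        clustering_coefficient=nx.average_clustering(g),
        average_path_length=float(apl),
        diameter=diam,
        n_components=len(components),
        modularity=q,
        n_modules=len(part),
        average_path_length_per_node=float(apl) / n,
        diameter_per_node=diam / n,
    )


def network_from_table(
    table: AsvTable,
    min_prevalence: float = 0.0,
    min_mean_relabund: float = 0.0,
    rho_min: float = 0.8,
    alpha: float = 0.05,
    force: bool = False,
) -> CoNetwork:
    """Convenience composition: filter -> Spearman -> threshold."""
    filtered = filter_taxa(table, min_prevalence, min_mean_relabund)
    corr = spearman_matrix(filtered, force=force)
    abund = filtered.relative_abundance().mean(axis=1)
    return build_network(corr, rho_min=rho_min, alpha=alpha, abundances=abund)


def per_group_networks(
    table: AsvTable,
    groups: pd.Series,
    **kwargs,
) -> dict[str, CoNetwork]:
    """Build one network per treatment group (columns split by label)."""
    nets = {}
    for level in pd.unique(groups):
        samples = groups.index[groups == level].tolist()
        nets[str(level)] = network_from_table(table.subset_samples(samples), **kwargs)
    return nets


__all__ = [
    "filter_taxa",
    "spearman_matrix",
    "build_network",
    "topology",
    "network_from_table",
    "per_group_networks",
    "louvain_partition",
    "average_degree",
    "density",
    "percent_reduction",
    "CorrelationResult",
    "CoNetwork",
    "TopologyMetrics",
]
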