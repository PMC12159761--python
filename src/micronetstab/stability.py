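"""Community cohesion, network robustness, vulnerability and complexity.

Cohesion follows the connectedness approach: each taxon's average positive
and negative (optionally null-model-corrected) Pearson correlation with all
other taxa, weighted by its relative abundance in each sample. The ratio of
absolute negative to positive cohesion serves as a community stability
index. Robustness simulates node removal (random or targeted) and tracks the
fraction of surviving nodes that keep at least one edge; vulnerability is
the worst-case relative drop in global efficiency from deleting one node.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .conet import CoNetwork, average_degree
from .tabio import AsvTable, DataValidationError

# ---------------------------------------------------------------------------
# cohesion
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohesionResult:
    """Per-taxon connectedness (positive/negative) and per-sample cohesion."""

    connectedness: pd.DataFrame  # index taxon, columns positive/negative
    cohesion: pd.DataFrame  # index sample, columns positive/negative
    null_model: str
    n_null: int
    seed: int | None


def cohesion(
    table: AsvTable,
    null_model: str = "taxa_shuffle",
    n_null: int = 200,
    seed: int | None = 0,
) -> CohesionResult:
    """Positive and negative cohesion per sample.

    Pairwise Pearson correlations of relative abundances are optionally
    corrected by subtracting the mean correlation under ``n_null``
    independent per-taxon shuffles across samples (``taxa_shuffle`` null).
    connectedness+ of a taxon is the mean of its positive corrected
    correlations with the other taxa (0 if none), connectedness- the mean of
    the negative ones; cohesion+- of a sample weights connectedness by
    relative abundance.
    """
    if null_model not in ("none", "taxa_shuffle"):
        raise ValueError(f"unknown null model {null_model!r}")
    if null_model == "taxa_shuffle" and n_null < 10:
        raise ValueError("taxa_shuffle needs n_null >= 10")

    rel = table.relative_abundance()
    variances = rel.var(axis=1)
    constant = variances.index[~(variances > 0)].tolist()
    if constant:
        warnings.warn(
            f"excluding {len(constant)} constant taxa from cohesion", stacklevel=2
        )
        rel = rel.drop(index=constant)
    if rel.shape[0] < 2:
        raise DataValidationError("cohesion needs at least 2 varying taxa")

    X = rel.to_numpy().T  # samples x taxa
    n_s, n_t = X.shape
    corr = np.corrcoef(X, rowvar=False)

    if null_model == "taxa_shuffle":
        rng = np.random.default_rng(seed)
        Xs = (X - X.mean(axis=0)) / X.std(axis=0)
        null_sum = np.zeros((n_t, n_t))
        for _ in range(n_null):
            perm = np.empty_like(Xs)
            for j in range(n_t):
                perm[:, j] = Xs[rng.permutation(n_s), j]
            # cross-correlation of observed taxon i with shuffled taxon j
            null_sum += Xs.T @ perm / n_s
        null_mean = null_sum / n_null
        null_mean = (null_mean + null_mean.T) / 2  # symmetrize i-vs-j direction
        corrected = corr - null_mean
    else:
        corrected = corr.copy()

    np.fill_diagonal(corrected, np.nan)
    pos = np.where(corrected > 0, corrected, np.nan)
    neg = np.where(corrected < 0, corrected, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows -> 0
        conn_pos = np.nan_to_num(np.nanmean(pos, axis=1))
        conn_neg = np.nan_to_num(np.nanmean(neg, axis=1))

    coh_pos = X @ conn_pos
    coh_neg = X @ conn_neg
    return CohesionResult(
        connectedness=pd.DataFrame(
            {"positive": conn_pos, "negative": conn_neg}, index=rel.index
        ),
        cohesion=pd.DataFrame(
            {"positive": coh_pos, "negative": coh_neg}, index=rel.columns
        ),
        null_model=null_model,
        n_null=n_null if null_model == "taxa_shuffle" else 0,
        seed=seed,
    )


def stability_ratio(result: CohesionResult, groups: pd.Series | None = None) -> pd.DataFrame:
    """Per-sample stability ratio |negative cohesion| / positive cohesion,
    with group (or overall) mean and standard error.

    Samples with non-positive positive cohesion get NaN.
    """
    coh = result.cohesion
    ratio = np.where(coh["positive"] > 0, np.abs(coh["negative"]) / coh["positive"], np.nan)
    per_sample = pd.DataFrame({"stability_ratio": ratio}, index=coh.index)
    if groups is not None:
        per_sample["group"] = pd.Series(groups).reindex(coh.index)
    return per_sample


def summarize_stability(per_sample: pd.DataFrame) -> pd.DataFrame:
    """Group mean +- SE of the stability ratio."""
    if "group" in per_sample.columns:
        grouped = per_sample.groupby("group")["stability_ratio"]
    else:
        grouped = per_sample.assign(group="all").groupby("group")["stability_ratio"]
    out = grouped.agg(["mean", "sem", "count"])
    out.columns = ["mean", "se", "n"]
    return out


# ---------------------------------------------------------------------------
# robustness
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RobustnessCurve:
    """Mean +- SD connectivity retention across node-removal fractions."""

    frame: pd.DataFrame  # columns fraction, mean, sd
    strategy: str
    n_repetitions: int
    seed: int

    def at(self, fraction: float) -> float:
        row = self.frame.loc[np.isclose(self.frame["fraction"], fraction)]
        if row.empty:
            raise KeyError(f"fraction {fraction} not on the curve")
        return float(row["mean"].iloc[0])


DEFAULT_FRACTIONS = tuple(np.round(np.arange(0.0, 1.0, 0.05), 2))


def robustness(
    net: CoNetwork,
    strategy: str = "random",
    fractions: tuple[float, ...] = DEFAULT_FRACTIONS,
    n_repetitions: int = 100,
    seed: int = 0,
) -> RobustnessCurve:
    """Node-removal robustness.

    Per repetition and fraction f, remove floor(f*N) nodes — uniformly at
    random, or highest-degree-first / highest-betweenness-first with random
    tie-breaking for targeted strategies — and record the fraction of
    remaining nodes that retain at least one edge. The f=0.5 point is the
    headline robustness value.
    """
    g = net.graph
    nodes = list(g.nodes)
    n = len(nodes)
    if n == 0:
        raise DataValidationError("empty network")
    if strategy not in ("random", "degree", "betweenness"):
        raise ValueError(f"unknown removal strategy {strategy!r}")

    if strategy == "degree":
        score = np.array([g.degree(v) for v in nodes], dtype=float)
    elif strategy == "betweenness":
        bc = nx.betweenness_centrality(g)
        score = np.array([bc[v] for v in nodes])
    else:
        score = None

    adj = {v: set(g.neighbors(v)) for v in nodes}
    rng = np.random.default_rng(seed)
    stats = np.zeros((n_repetitions, len(fractions)))
    for rep in range(n_repetitions):
        if strategy == "random":
            order = rng.permutation(n)
        else:
            # descending score, random tie-break via jittered sort key
            order = np.lexsort((rng.random(n), -score))
        ordered = [nodes[i] for i in order]
        for fi, f in enumerate(fractions):
            n_remove = int(np.floor(f * n))
            removed = set(ordered[:n_remove])
            survivors = [v for v in nodes if v not in removed]
            if not survivors:
                stats[rep, fi] = 0.0
                continue
            connected = sum(1 for v in survivors if adj[v] - removed)
            stats[rep, fi] = connected / len(survivors)

    frame = pd.DataFrame(
        {
            "fraction": list(fractions),
            "mean": stats.mean(axis=0),
            "sd": stats.std(axis=0, ddof=1) if n_repetitions > 1 else 0.0,
        }
    )
    return RobustnessCurve(
        frame=frame, strategy=strategy, n_repetitions=n_repetitions, seed=seed
    )


# ---------------------------------------------------------------------------
# vulnerability and complexity
# ---------------------------------------------------------------------------


def global_efficiency(graph: nx.Graph) -> float:
    """Mean inverse shortest-path length over all node pairs; disconnected
    pairs contribute 0."""
    n = graph.number_of_nodes()
    if n < 2:
        return 0.0
    total = 0.0
    for _, lengths in nx.all_pairs_shortest_path_length(graph):
        total += sum(1.0 / d for d in lengths.values() if d > 0)
    return total / (n * (n - 1))


def vulnerability(net: CoNetwork) -> float:
    """Worst-case relative efficiency loss from a single node deletion:
    max_i (E - E_i) / E with E the global efficiency of the full network."""
    g = net.graph
    if g.number_of_nodes() < 3:
        raise DataValidationError("vulnerability needs at least 3 nodes")
    e_full = global_efficiency(g)
    if e_full == 0:
        raise DataValidationError("network has no edges")
    worst = -np.inf
    for v in g.nodes:
        sub = g.subgraph([u for u in g.nodes if u != v])
        worst = max(worst, (e_full - global_efficiency(sub)) / e_full)
    return float(worst)


def complexity(net: CoNetwork) -> float:
    """Network complexity proxy: linkage density (average degree, 2E/N)."""
    if net.n_nodes == 0:
        raise DataValidationError("empty network")
    return average_degree(net.n_nodes, net.n_edges)


__all__ = [
    "cohesion",
    "stability_ratio",
    "summarize_stability",
    "robustness",
    "global_efficiency",
    "vulnerability",
    "complexity",
    "CohesionResult",
    "RobustnessCurve",
]
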