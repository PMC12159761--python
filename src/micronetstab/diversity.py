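"""Rarefaction, alpha diversity, Bray-Curtis/PCoA ordination and PERMANOVA.

Alpha indices use the conventional definitions: Shannon with natural log,
bias-corrected Chao1 (so doubleton-free samples are defined), Simpson
concentration and its inverse, and Faith's phylogenetic diversity under the
rooted convention (the root-to-subtree path counts). PERMANOVA partitions
the squared distance matrix by group and assesses the pseudo-F by label
permutation with the +1 convention, so p is never zero.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode
from statsmodels.stats.multitest import multipletests

from .tabio import AsvTable, DataValidationError, match_tree_to_table

# ---------------------------------------------------------------------------
# rarefaction
# ---------------------------------------------------------------------------


def rarefy(
    table: AsvTable,
    depth: int,
    seed: int = 0,
    drop_small: bool = False,
) -> AsvTable:
    """Subsample every sample without replacement to exactly ``depth`` reads
    (multivariate hypergeometric draw).

    Samples with fewer than ``depth`` total reads raise an error unless
    ``drop_small`` removes them instead.
    """
    depth = int(depth)
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    sums = table.sample_sums()
    small = sums.index[sums < depth].tolist()
    if small and not drop_small:
        raise DataValidationError(
            f"samples below rarefaction depth {depth}: {small}"
        )
    keep = [s for s in table.sample_ids if s not in small]
    if len(keep) < 2:
        raise DataValidationError("fewer than 2 samples remain after depth filter")
    rng = np.random.default_rng(seed)
    out = {}
    for s in keep:
        col = table.counts[s].to_numpy()
        if col.sum() == depth:
            out[s] = col
        else:
            out[s] = rng.multivariate_hypergeometric(col, depth)
    df = pd.DataFrame(out, index=table.counts.index)
    return AsvTable(df)


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------


def _alpha_one(counts: np.ndarray) -> dict[str, float]:
    total = counts.sum()
    if total == 0:
        return {
            "observed_taxa": np.nan,
            "chao1": np.nan,
            "shannon": np.nan,
            "simpson": np.nan,
            "inv_simpson": np.nan,
        }
    present = counts[counts > 0]
    s_obs = present.size
    f1 = int((present == 1).sum())
    f2 = int((present == 2).sum())
    chao1 = s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    p = present / total
    shannon = float(-(p * np.log(p)).sum())
    simpson = float((p**2).sum())
    return {
        "observed_taxa": float(s_obs),
        "chao1": float(chao1),
        "shannon": shannon,
        "simpson": simpson,
        "inv_simpson": 1.0 / simpson,
    }


def faith_pd(counts: np.ndarray, taxa: list[str], tree: TreeNode) -> float:
    """Total branch length of the rooted subtree spanning the present taxa."""
    present = [t for t, c in zip(taxa, counts) if c > 0]
    if not present:
        return np.nan
    if len(present) == 1:
        # path from the single tip to the root
        tip = tree.find(present[0])
        length = 0.0
        node = tip
        while node.parent is not None:
            length += node.length or 0.0
            node = node.parent
        return length
    sub = tree.shear(present)
    return float(sum(n.length or 0.0 for n in sub.traverse() if n.length is not None))


def alpha_diversity(table: AsvTable, tree: TreeNode | None = None) -> pd.DataFrame:
    """Per-sample alpha diversity (observed taxa, Chao1, Shannon, Simpson,
    inverse Simpson, and Faith PD when a tree is supplied).

    All-zero samples get NaN across the board rather than a misleading 0.
    """
    rows = {}
    taxa = table.taxon_ids
    matched = match_tree_to_table(tree, table) if tree is not None else None
    for s in table.sample_ids:
        col = table.counts[s].to_numpy()
        rec = _alpha_one(col)
        if matched is not None:
            rec["faith_pd"] = faith_pd(col, taxa, matched) if col.sum() > 0 else np.nan
        rows[s] = rec
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# beta diversity
# ---------------------------------------------------------------------------


def bray_curtis(table: AsvTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between samples, sum|x-y| / sum(x+y)."""
    sums = table.sample_sums()
    zero = sums.index[sums == 0].tolist()
    if len(zero) >= 2:
        raise DataValidationError(
            f"Bray-Curtis undefined between all-zero samples: {zero}"
        )
    X = table.counts.to_numpy().T.astype(float)
    d = pdist(X, metric="braycurtis")
    return DistanceMatrix(squareform(d), ids=table.sample_ids)


@dataclass(frozen=True)
class OrdinationResult:
    """Principal-coordinates embedding: sample coordinates on the positive
    axes, all eigenvalues (descending), and per-axis variance proportions."""

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray


def pcoa(dm: DistanceMatrix, correction: str | None = None) -> OrdinationResult:
    """Classical PCoA: Gower double-centering of -D^2/2 and eigendecomposition.

    Coordinates are eigenvectors scaled by sqrt(eigenvalue) for positive
    eigenvalues; negative eigenvalues are excluded from the variance
    denominator. ``correction='cailliez'`` adds the Cailliez constant to the
    off-diagonal distances first, removing negative eigenvalues.
    """
    D = np.asarray(dm.data, dtype=float)
    if not np.allclose(D, D.T):
        raise DataValidationError("distance matrix must be symmetric")
    n = D.shape[0]
    if correction == "cailliez":
        D = D + _cailliez_constant(D) * (1 - np.eye(n))
    elif correction is not None:
        raise ValueError(f"unknown correction {correction!r}")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    B = (B + B.T) / 2
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = 1e-9 * max(abs(evals[0]), 1.0)
    pos = evals > tol
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    axes = [f"PC{i + 1}" for i in range(pos.sum())]
    prop = evals[pos] / evals[pos].sum()
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=list(dm.ids), columns=axes),
        eigenvalues=evals,
        proportion_explained=prop,
    )


def _cailliez_constant(D: np.ndarray) -> float:
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    d1 = -0.5 * J @ (D**2) @ J
    d2 = -0.5 * J @ D @ J
    zero = np.zeros((n, n))
    block = np.block([[zero, 2 * d1], [-np.eye(n), -4 * d2]])
    ev = np.linalg.eigvals(block)
    c = float(np.max(ev.real))
    return max(c, 0.0)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_F: float
    r2: float
    p_value: float
    n_permutations: int
    seed: int
    n_samples: int
    n_groups: int


def _ss_within(d2: np.ndarray, group_indices: list[np.ndarray]) -> float:
    ss = 0.0
    for idx in group_indices:
        ss += d2[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
    return ss


def permanova(
    dm: DistanceMatrix,
    groups,
    n_permutations: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    SS_total = sum_{i<j} d_ij^2 / N; SS_within pools within-group squared
    distances scaled by group size; pseudo-F = (SS_between/(k-1)) /
    (SS_within/(N-k)). The p-value counts permuted F >= observed with the
    (1 + x)/(1 + n) convention.
    """
    groups = pd.Series(np.asarray(groups), index=list(dm.ids))
    labels = groups.to_numpy()
    n = len(labels)
    uniq, inv = np.unique(labels, return_inverse=True)
    k = uniq.size
    if k < 2:
        raise DataValidationError("PERMANOVA needs at least 2 groups")
    sizes = np.bincount(inv)
    if (sizes < 2).any():
        bad = uniq[sizes < 2].tolist()
        raise DataValidationError(f"groups with fewer than 2 samples: {bad}")

    d2 = np.asarray(dm.data, dtype=float) ** 2
    ss_total = d2.sum() / (2.0 * n)
    group_pos = [np.flatnonzero(inv == g) for g in range(k)]
    ss_w = _ss_within(d2, group_pos)
    ss_b = ss_total - ss_w
    f_obs = (ss_b / (k - 1)) / (ss_w / (n - k))
    r2 = ss_b / ss_total

    rng = np.random.default_rng(seed)
    # vectorized permutation null: gather within-group blocks for all
    # permutations at once
    perms = np.array([rng.permutation(n) for _ in range(n_permutations)])
    ss_w_perm = np.zeros(n_permutations)
    for g in range(k):
        idx = perms[:, group_pos[g]]  # (n_perm, n_g)
        block = d2[idx[:, :, None], idx[:, None, :]]
        ss_w_perm += block.sum(axis=(1, 2)) / (2.0 * sizes[g])
    ss_b_perm = ss_total - ss_w_perm
    f_perm = (ss_b_perm / (k - 1)) / (ss_w_perm / (n - k))
    p = (1.0 + np.sum(f_perm >= f_obs)) / (1.0 + n_permutations)

    return PermanovaResult(
        pseudo_F=float(f_obs),
        r2=float(r2),
        p_value=float(p),
        n_permutations=n_permutations,
        seed=seed,
        n_samples=n,
        n_groups=k,
    )


def pairwise_permanova(
    dm: DistanceMatrix,
    groups,
    n_permutations: int = 999,
    seed: int = 0,
    correction: str = "fdr_bh",
) -> pd.DataFrame:
    """PERMANOVA on every group pair (deterministic pair order) with
    multiplicity-adjusted p-values."""
    groups = pd.Series(np.asarray(groups), index=list(dm.ids))
    levels = sorted(groups.unique().tolist())
    rows = []
    for a, b in itertools.combinations(levels, 2):
        ids = groups.index[groups.isin([a, b])].tolist()
        sub = dm.filter(ids)
        res = permanova(sub, groups.loc[ids], n_permutations=n_permutations, seed=seed)
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "pseudo_F": res.pseudo_F,
                "r2": res.r2,
                "p_value": res.p_value,
            }
        )
    df = pd.DataFrame(rows)
    df["p_adj"] = multipletests(df["p_value"], method=correction)[1]
    return df


__all__ = [
    "rarefy",
    "alpha_diversity",
    "faith_pd",
    "bray_curtis",
    "pcoa",
    "OrdinationResult",
    "permanova",
    "pairwise_permanova",
    "PermanovaResult",
]
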