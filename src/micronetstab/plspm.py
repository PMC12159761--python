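"""Partial least squares path modeling (PLS-PM).

Component-based structural equation modeling: each latent variable is a
weighted composite of its manifest columns, estimated by the classical
Lohmoller iteration (inner approximation by centroid / factorial / path
weighting, outer approximation by mode A correlations or mode B
regressions), followed by OLS path coefficients among the latent scores,
per-endogenous R-squared and the goodness of fit
GoF = sqrt(mean communality x mean R-squared). Uncertainty comes from a
nonparametric bootstrap over samples with percentile confidence intervals.

The API mirrors statsmodels: ``PlsPathModel(data, spec).fit()`` returns a
``PlsPathResults`` with a ``summary()`` table and a ``bootstrap()`` method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml


class ConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class PlsPmSpec:
    """Latent-block definitions and the inner (structural) model.

    ``blocks`` maps latent names to manifest column lists (order defines the
    causal order); ``paths`` lists directed (source, target) latent pairs and
    must be acyclic with respect to the block order; ``modes`` gives the
    measurement mode per block ('A' reflective, 'B' formative; default A).
    """

    blocks: dict[str, list[str]]
    paths: list[tuple[str, str]]
    modes: dict[str, str] = field(default_factory=dict)
    scheme: str = "path"
    tolerance: float = 1e-7
    max_iterations: int = 300

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("spec needs at least one block")
        for name, cols in self.blocks.items():
            if not cols:
                raise ValueError(f"block {name!r} has no manifest columns")
        order = {name: i for i, name in enumerate(self.blocks)}
        for src, dst in self.paths:
            if src not in order or dst not in order:
                raise ValueError(f"path {src}->{dst} references unknown block")
            if order[src] >= order[dst]:
                raise ValueError(
                    f"path {src}->{dst} violates the acyclic block order"
                )
        if self.scheme not in ("centroid", "factorial", "path"):
            raise ValueError(f"unknown inner scheme {self.scheme!r}")
        for name, mode in self.modes.items():
            if mode not in ("A", "B"):
                raise ValueError(f"mode of block {name!r} must be 'A' or 'B'")

    @property
    def latents(self) -> list[str]:
        return list(self.blocks)

    @property
    def manifests(self) -> list[str]:
        return [c for cols in self.blocks.values() for c in cols]

    def mode(self, block: str) -> str:
        return self.modes.get(block, "A")

    def predecessors(self, block: str) -> list[str]:
        return [s for s, d in self.paths if d == block]

    def successors(self, block: str) -> list[str]:
        return [d for s, d in self.paths if s == block]

    @property
    def endogenous(self) -> list[str]:
        return [b for b in self.blocks if self.predecessors(b)]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PlsPmSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        blocks = {str(k): [str(c) for c in v] for k, v in raw["blocks"].items()}
        paths = [(str(a), str(b)) for a, b in (p if isinstance(p, (list, tuple)) else p.split("->") for p in raw["paths"])]
        paths = [(a.strip(), b.strip()) for a, b in paths]
        return cls(
            blocks=blocks,
            paths=paths,
            modes={str(k): str(v) for k, v in raw.get("modes", {}).items()},
            scheme=raw.get("scheme", "path"),
            tolerance=float(raw.get("tolerance", 1e-7)),
            max_iterations=int(raw.get("max_iterations", 300)),
        )


def _standardize(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("constant manifest column")
    return (X - X.mean(axis=0)) / sd


class PlsPathModel:
    """PLS path model bound to a data frame and a block/path specification.

    Rows with any missing manifest are dropped (listwise deletion).
    """

    def __init__(self, data: pd.DataFrame, spec: PlsPmSpec):
        missing = [c for c in spec.manifests if c not in data.columns]
        if missing:
            raise ValueError(f"data lacks manifest columns: {missing}")
        frame = data[spec.manifests].apply(pd.to_numeric).dropna()
        n = frame.shape[0]
        max_pred = max((len(spec.predecessors(b)) for b in spec.blocks), default=0)
        if n <= max_pred + 1:
            raise ValueError(
                f"{n} complete rows is too few for {max_pred} predictors"
            )
        self.data = frame
        self.spec = spec

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, spec: PlsPmSpec) -> "PlsPathModel":
        return cls(data, spec)

    def fit(self) -> "PlsPathResults":
        spec = self.spec
        X = _standardize(self.data.to_numpy(dtype=float))
        n = X.shape[0]
        cols = {c: i for i, c in enumerate(self.data.columns)}
        block_idx = {b: [cols[c] for c in spec.blocks[b]] for b in spec.blocks}
        latents = spec.latents

        # adjacency of the inner model (undirected for the inner weighting)
        neighbors = {b: set(spec.predecessors(b)) | set(spec.successors(b)) for b in latents}

        weights = {b: np.ones(len(block_idx[b])) for b in latents}
        scores = {}

        def rescale(y: np.ndarray) -> np.ndarray:
            sd = y.std(ddof=1)
            if sd == 0:
                raise ConvergenceError("degenerate latent score (zero variance)")
            return y / sd

        for b in latents:
            scores[b] = rescale(X[:, block_idx[b]] @ weights[b])

        converged = False
        for iteration in range(1, spec.max_iterations + 1):
            # inner approximation
            inner = {}
            for b in latents:
                z = np.zeros(n)
                if spec.scheme == "path":
                    preds = spec.predecessors(b)
                    if preds:
                        P = np.column_stack([scores[p] for p in preds])
                        coef, *_ = np.linalg.lstsq(P, scores[b], rcond=None)
                        z = z + P @ coef
                    for s in spec.successors(b):
                        r = np.corrcoef(scores[b], scores[s])[0, 1]
                        z = z + r * scores[s]
                else:
                    for c in neighbors[b]:
                        r = np.corrcoef(scores[b], scores[c])[0, 1]
                        e = np.sign(r) if spec.scheme == "centroid" else r
                        z = z + e * scores[c]
                if not neighbors[b]:  # isolated block keeps its own score
                    z = scores[b]
                inner[b] = rescale(z)

            # outer approximation
            new_weights = {}
            new_scores = {}
            for b in latents:
                Xb = X[:, block_idx[b]]
                if spec.mode(b) == "A":
                    w = Xb.T @ inner[b] / n
                else:
                    w, *_ = np.linalg.lstsq(Xb, inner[b], rcond=None)
                y = Xb @ w
                sd = y.std(ddof=1)
                if sd == 0:
                    raise ConvergenceError(f"block {b!r} collapsed to zero variance")
                w = w / sd
                # sign convention: positive correlation with first manifest
                if np.corrcoef(Xb @ w, Xb[:, 0])[0, 1] < 0:
                    w = -w
                new_weights[b] = w
                new_scores[b] = Xb @ w

            delta = max(
                np.max(np.abs(new_weights[b] - weights[b])) for b in latents
            )
            weights, scores = new_weights, new_scores
            if delta < spec.tolerance:
                converged = True
                break
        if not converged:
            raise ConvergenceError(
                f"outer weights did not converge in {spec.max_iterations} iterations"
            )

        # path coefficients by OLS among latent scores
        path_mat = pd.DataFrame(0.0, index=latents, columns=latents)
        r2 = {}
        for b in spec.endogenous:
            preds = spec.predecessors(b)
            P = np.column_stack([scores[p] for p in preds])
            coef, *_ = np.linalg.lstsq(P, scores[b], rcond=None)
            for p, c in zip(preds, coef):
                path_mat.loc[b, p] = float(c)
            fitted = P @ coef
            r2[b] = float(1.0 - np.sum((scores[b] - fitted) ** 2) / np.sum(scores[b] ** 2))

        loadings = {}
        communalities = {}
        for b in latents:
            for ci, c in enumerate(spec.blocks[b]):
                load = float(np.corrcoef(X[:, block_idx[b][ci]], scores[b])[0, 1])
                loadings[c] = load
                communalities[c] = load**2

        mean_comm = float(np.mean(list(communalities.values())))
        mean_r2 = float(np.mean(list(r2.values()))) if r2 else np.nan
        gof_value = float(np.sqrt(mean_comm * mean_r2)) if r2 else np.nan

        score_frame = pd.DataFrame(
            {b: scores[b] for b in latents}, index=self.data.index
        )
        weight_series = pd.Series(
            {
                c: float(weights[b][ci])
                for b in latents
                for ci, c in enumerate(spec.blocks[b])
            },
            name="outer_weight",
        )
        return PlsPathResults(
            model=self,
            outer_weights=weight_series,
            loadings=pd.Series(loadings, name="loading"),
            communalities=pd.Series(communalities, name="communality"),
            scores=score_frame,
            path_coefficients=path_mat,
            r2=r2,
            gof=gof_value,
            n_iterations=iteration,
        )


@dataclass
class PlsPathResults:
    """Fitted PLS path model: composites, paths, fit indices, bootstrap."""

    model: PlsPathModel
    outer_weights: pd.Series
    loadings: pd.Series
    communalities: pd.Series
    scores: pd.DataFrame
    path_coefficients: pd.DataFrame
    r2: dict[str, float]
    gof: float
    n_iterations: int
    boot: pd.DataFrame | None = None

    def path_table(self) -> pd.DataFrame:
        rows = [
            {
                "source": src,
                "target": dst,
                "coefficient": float(self.path_coefficients.loc[dst, src]),
            }
            for src, dst in self.model.spec.paths
        ]
        df = pd.DataFrame(rows)
        if self.boot is not None:
            df = df.merge(self.boot, on=["source", "target"], how="left")
        return df

    def bootstrap(
        self, n_boot: int = 500, seed: int = 0, ci_level: float = 0.95
    ) -> pd.DataFrame:
        """Percentile bootstrap over samples; a path is flagged significant
        when its CI excludes zero. Replicates with a constant manifest are
        skipped (counted in ``n_failed``)."""
        if n_boot <= 0:
            self.boot = None
            return pd.DataFrame()
        spec = self.model.spec
        data = self.model.data
        rng = np.random.default_rng(seed)
        draws = {pair: [] for pair in spec.paths}
        n_failed = 0
        n = data.shape[0]
        for _ in range(n_boot):
            idx = rng.integers(0, n, size=n)
            sample = data.iloc[idx]
            try:
                res = PlsPathModel(sample, spec).fit()
            except (ValueError, ConvergenceError):
                n_failed += 1
                continue
            for src, dst in spec.paths:
                draws[(src, dst)].append(res.path_coefficients.loc[dst, src])
        if n_failed:
            warnings.warn(f"{n_failed}/{n_boot} bootstrap refits skipped", stacklevel=2)
        lo_q, hi_q = (1 - ci_level) / 2, 1 - (1 - ci_level) / 2
        rows = []
        for src, dst in spec.paths:
            vals = np.asarray(draws[(src, dst)])
            if vals.size == 0:
                rows.append(
                    {"source": src, "target": dst, "boot_se": np.nan,
                     "ci_low": np.nan, "ci_high": np.nan, "significant": False}
                )
                continue
            lo, hi = np.quantile(vals, [lo_q, hi_q])
            rows.append(
                {
                    "source": src,
                    "target": dst,
                    "boot_se": float(vals.std(ddof=1)) if vals.size > 1 else np.nan,
                    "ci_low": float(lo),
                    "ci_high": float(hi),
                    "significant": bool(lo > 0 or hi < 0),
                }
            )
        self.boot = pd.DataFrame(rows)
        return self.boot

    def summary(self) -> str:
        lines = [
            "PLS path model results",
            "======================",
            f"n samples: {self.scores.shape[0]}   iterations: {self.n_iterations}"
            f"   scheme: {self.model.spec.scheme}",
            f"goodness of fit: {self.gof:.4f}" if np.isfinite(self.gof) else "goodness of fit: n/a",
            "",
            "Inner paths:",
        ]
        table = self.path_table()
        for row in table.itertuples(index=False):
            extra = ""
            if self.boot is not None and hasattr(row, "ci_low") and np.isfinite(row.ci_low):
                star = "*" if row.significant else " "
                extra = f"  [{row.ci_low: .3f}, {row.ci_high: .3f}]{star}"
            lines.append(
                f"  {row.source} -> {row.target}: {row.coefficient: .4f}{extra}"
            )
        lines.append("")
        lines.append("R2 per endogenous latent:")
        for b, v in self.r2.items():
            lines.append(f"  {b}: {v:.4f}")
        return "\n".join(lines)


def fit_plspm(data: pd.DataFrame, spec: PlsPmSpec) -> PlsPathResults:
    """Functional wrapper: build and fit a :class:`PlsPathModel`."""
    return PlsPathModel(data, spec).fit()


def bootstrap_paths(
    results: PlsPathResults, n_boot: int = 500, seed: int = 0
) -> pd.DataFrame:
    """Functional wrapper for :meth:`PlsPathResults.bootstrap`."""
    return results.bootstrap(n_boot=n_boot, seed=seed)


def gof(results: PlsPathResults) -> float:
    """Goodness of fit, sqrt(mean communality x mean endogenous R2)."""
    return results.gof


__all__ = [
    "PlsPmSpec",
    "PlsPathModel",
    "PlsPathResults",
    "fit_plspm",
    "bootstrap_paths",
    "gof",
    "ConvergenceError",
]
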