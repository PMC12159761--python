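"""Synthetic amplicon communities with known ground truth.

Emulates a three-treatment field design (CK, M, bioM; six replicate plots
each): overdispersed ASV counts with uneven library sizes, planted blocks of
correlated taxa, treatment-specific abundance shifts, and soil covariates and
plant outcomes generated from a known acyclic path model. Every downstream
stage (network inference, community detection, PLS path modeling) therefore
has a recoverable answer.

Count model: each taxon carries a latent Gaussian factor with block
correlation structure (``rho_in`` within planted modules, ``rho_out``
between). The latent is exponentiated into a log-normal relative abundance,
scaled by treatment effects for effect taxa, and sampled as a negative
binomial at a sample-specific log-normal library depth. Rank correlations
survive the monotone transform, so the planted blocks are recoverable by
Spearman-based network inference; zero inflation arises naturally from the
counting process rather than a separate zero component.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .tabio import AsvTable, SampleMetadata

LATENTS = ("treatment", "soil", "community", "plant")

#: default inner path model among the latent variables (lower-triangular in
#: the order treatment -> soil -> community -> plant)
DEFAULT_PATHS: dict[tuple[str, str], float] = {
    ("treatment", "soil"): 0.6,
    ("treatment", "community"): 0.5,
    ("soil", "community"): 0.4,
    ("soil", "plant"): 0.3,
    ("community", "plant"): 0.5,
}

#: realistic units for the soil covariates (mean, sd), loosely calibrated to
#: published rhizosphere chemistry tables; only the affine scale — the
#: generative signal is the standardized latent path model.
SOIL_COVARIATES: dict[str, tuple[float, float]] = {
    "pH": (6.6, 0.15),
    "SMC": (13.1, 0.9),
    "NH4": (3.2, 0.35),
    "NO3": (14.3, 3.0),
    "IN": (17.5, 3.3),
    "DOC": (17.3, 2.0),
    "DON": (0.31, 0.09),
    "TC": (43.5, 1.8),
    "TN": (2.68, 0.2),
}

PLANT_OUTCOMES: dict[str, tuple[float, float]] = {
    "biomass": (52.0, 8.0),
    "yield": (2.9, 0.45),
}

COMMUNITY_MANIFESTS: dict[str, tuple[float, float]] = {
    "comm_axis1": (0.0, 1.0),
    "comm_axis2": (0.0, 1.0),
}


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic study.

    Defaults mirror the emulated design: 3 treatments x 6 replicates,
    desk-scale taxon count, library sizes around the study's rarefaction
    depth, and moderate treatment effects.
    """

    n_taxa: int = 150
    n_samples_per_group: int = 6
    groups: tuple[str, ...] = ("CK", "M", "bioM")
    n_modules: int = 4
    rho_in: float = 0.7
    rho_out: float = 0.0
    depth_mean: float = 40_000.0
    depth_cv: float = 0.3
    dispersion: float = 0.5
    effect_taxa_frac: float = 0.2
    effect_logfc: float = 1.0
    base_log_sd: float = 1.5
    latent_scale: float = 1.0
    meta_noise_sd: float = 0.3
    path_coefficients: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_PATHS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa <= 0 or self.n_samples_per_group <= 0:
            raise ValueError("n_taxa and n_samples_per_group must be positive")
        if self.n_taxa < self.n_modules:
            raise ValueError("n_taxa must be at least n_modules")
        if not (0 <= self.rho_in < 1):
            raise ValueError("rho_in must lie in [0, 1)")
        if not (0 <= self.rho_out <= self.rho_in):
            raise ValueError("rho_out must lie in [0, rho_in]")
        if self.rho_out >= self.rho_in and self.rho_in > 0 and self.n_modules > 1:
            raise ValueError("rho_out must be smaller than rho_in")
        if not (0 <= self.effect_taxa_frac <= 1):
            raise ValueError("effect_taxa_frac must lie in [0, 1]")
        for name in ("depth_mean", "depth_cv", "dispersion", "effect_logfc",
                     "meta_noise_sd", "base_log_sd", "latent_scale"):
            v = float(getattr(self, name))
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite")

    @property
    def n_samples(self) -> int:
        return self.n_samples_per_group * len(self.groups)

    def sample_ids(self) -> list[str]:
        return [
            f"{g}_{r + 1}"
            for g in self.groups
            for r in range(self.n_samples_per_group)
        ]

    def taxon_ids(self) -> list[str]:
        width = len(str(self.n_taxa))
        return [f"ASV{i + 1:0{width}d}" for i in range(self.n_taxa)]


@dataclass(frozen=True)
class GroundTruth:
    """Planted structure: module memberships, treatment-affected taxa, and
    the true inner path-coefficient matrix (lower-triangular, acyclic)."""

    module_assignment: pd.Series
    true_effect_taxa: dict[str, dict[str, float]]
    true_paths: pd.DataFrame

    def __post_init__(self) -> None:
        upper = np.triu(self.true_paths.to_numpy(), k=0)
        if np.any(upper != 0):
            raise ValueError("true_paths must be strictly lower-triangular (acyclic)")


def _path_matrix(coefficients: dict[tuple[str, str], float]) -> pd.DataFrame:
    mat = pd.DataFrame(0.0, index=LATENTS, columns=LATENTS)
    order = {name: i for i, name in enumerate(LATENTS)}
    for (src, dst), coef in coefficients.items():
        if src not in order or dst not in order:
            raise ValueError(f"unknown latent in path {(src, dst)}")
        if order[src] >= order[dst]:
            raise ValueError(f"path {src}->{dst} violates the causal order")
        mat.loc[dst, src] = float(coef)
    return mat


def generate_community(config: SynthConfig) -> tuple[AsvTable, GroundTruth]:
    """Draw an ASV count table with planted correlation modules and
    treatment shifts; returns the table and its ground truth."""
    rng = np.random.default_rng(config.seed)
    taxa = config.taxon_ids()
    samples = config.sample_ids()
    n_t, n_s = config.n_taxa, config.n_samples

    modules = np.arange(n_t) % config.n_modules
    rng.shuffle(modules)

    # latent block-correlated Gaussians: shared global factor (rho_out),
    # module factor (rho_in - rho_out), idiosyncratic remainder
    g = rng.standard_normal(n_s)
    u = rng.standard_normal((config.n_modules, n_s))
    e = rng.standard_normal((n_t, n_s))
    z = (
        np.sqrt(config.rho_out) * g[None, :]
        + np.sqrt(config.rho_in - config.rho_out) * u[modules, :]
        + np.sqrt(1.0 - config.rho_in) * e
    )

    base = rng.normal(0.0, config.base_log_sd, size=n_t)
    log_abund = base[:, None] + config.latent_scale * z

    # treatment effects: a fixed fraction of taxa shifts (random sign) in the
    # non-reference groups
    n_eff = int(round(config.effect_taxa_frac * n_t))
    effect_taxa: dict[str, dict[str, float]] = {}
    group_of_sample = np.repeat(np.arange(len(config.groups)), config.n_samples_per_group)
    for gi, group in enumerate(config.groups):
        if gi == 0 or n_eff == 0:
            effect_taxa[group] = {}
            continue
        idx = rng.choice(n_t, size=n_eff, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_eff)
        shifts = {taxa[i]: float(s * config.effect_logfc) for i, s in zip(idx, signs)}
        effect_taxa[group] = shifts
        cols = group_of_sample == gi
        for i, s in zip(idx, signs):
            log_abund[i, cols] += s * config.effect_logfc

    rel = np.exp(log_abund)
    rel /= rel.sum(axis=0, keepdims=True)

    depth_sigma = np.sqrt(np.log1p(config.depth_cv**2))
    depth_mu = np.log(config.depth_mean) - depth_sigma**2 / 2
    depths = rng.lognormal(depth_mu, depth_sigma, size=n_s)

    mu = rel * depths[None, :]
    if config.dispersion > 0:
        # gamma-Poisson mixture: var = mu + dispersion * mu^2
        shape = 1.0 / config.dispersion
        lam = rng.gamma(shape, mu * config.dispersion)
        counts = rng.poisson(lam)
    else:
        counts = rng.poisson(mu)

    table = AsvTable(pd.DataFrame(counts, index=taxa, columns=samples))
    truth = GroundTruth(
        module_assignment=pd.Series(modules, index=taxa, name="module"),
        true_effect_taxa=effect_taxa,
        true_paths=_path_matrix(config.path_coefficients),
    )
    return table, truth


def generate_metadata(config: SynthConfig, truth: GroundTruth) -> SampleMetadata:
    """Generate soil covariates and plant outcomes from the true path model.

    Latent scores follow the acyclic chain treatment -> soil -> community ->
    plant. The planted path coefficients are standardized: each endogenous
    latent's structural noise variance is set so its population variance is
    1, which makes the generative coefficients directly comparable to fitted
    standardized path coefficients. Manifest columns are affine rescalings
    of their latent plus independent measurement noise of standard deviation
    ``meta_noise_sd``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    samples = config.sample_ids()
    n = config.n_samples
    if n != len(samples):
        raise ValueError("config sample layout inconsistent")

    group_idx = np.repeat(np.arange(len(config.groups)), config.n_samples_per_group)
    raw_score = group_idx.astype(float)
    treatment = (raw_score - raw_score.mean()) / raw_score.std()

    paths = truth.true_paths
    scores = {"treatment": treatment}
    # population covariance among latents, built along the causal order so
    # each endogenous latent comes out with unit variance
    cov = pd.DataFrame(0.0, index=LATENTS, columns=LATENTS)
    cov.loc["treatment", "treatment"] = 1.0
    for latent in LATENTS[1:]:
        coefs = paths.loc[latent]
        parents = [p for p in LATENTS if coefs.get(p, 0.0)]
        val = np.zeros(n)
        explained = 0.0
        for p in parents:
            val = val + coefs[p] * scores[p]
            for q in parents:
                explained += coefs[p] * coefs[q] * cov.loc[p, q]
        if explained > 1.0 + 1e-9:
            raise ValueError(
                f"path coefficients into {latent!r} imply variance > 1 "
                f"({explained:.3f}); shrink them"
            )
        noise_sd = np.sqrt(max(1.0 - explained, 0.0))
        val = val + rng.normal(0.0, 1.0, size=n) * noise_sd
        scores[latent] = val
        for other in LATENTS:
            c = sum(coefs[p] * cov.loc[p, other] for p in parents)
            cov.loc[latent, other] = cov.loc[other, latent] = c
        cov.loc[latent, latent] = 1.0

    frame = pd.DataFrame(index=pd.Index(samples, name="sample_id"))
    frame["group"] = np.repeat(list(config.groups), config.n_samples_per_group)
    frame["treatment_score"] = scores["treatment"]

    def manifest(latent: str, mean: float, sd: float) -> np.ndarray:
        noisy = scores[latent] + rng.normal(0.0, config.meta_noise_sd, size=n)
        return mean + sd * noisy

    for col, (mean, sd) in SOIL_COVARIATES.items():
        frame[col] = manifest("soil", mean, sd)
    for col, (mean, sd) in COMMUNITY_MANIFESTS.items():
        frame[col] = manifest("community", mean, sd)
    for col, (mean, sd) in PLANT_OUTCOMES.items():
        frame[col] = manifest("plant", mean, sd)

    return SampleMetadata(frame, group_col="group")


def generate_tree(taxa: Sequence[str], seed: int = 0) -> str:
    """Random rooted bifurcating tree over ``taxa`` as a Newick string.

    Built by coalescent-style random pairwise joins with unit-exponential
    branch lengths; n taxa yield n-1 internal nodes.
    """
    taxa = list(taxa)
    if len(set(taxa)) != len(taxa):
        dups = sorted({t for t in taxa if taxa.count(t) > 1})
        raise ValueError(f"duplicate taxon identifiers: {dups}")
    if len(taxa) == 0:
        raise ValueError("need at least one taxon")
    rng = np.random.default_rng(seed)
    nodes = [str(t) for t in taxa]
    if len(nodes) == 1:
        return f"{nodes[0]}:{rng.exponential(1.0):.6f};"
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        bi, bj = rng.exponential(1.0, size=2)
        merged = f"({nodes[i]}:{max(bi, 1e-9):.6f},{nodes[j]}:{max(bj, 1e-9):.6f})"
        nodes[i] = merged
        nodes.pop(j)
    return nodes[0] + ";"


__all__ = [
    "SynthConfig",
    "GroundTruth",
    "DEFAULT_PATHS",
    "LATENTS",
    "generate_community",
    "generate_metadata",
    "generate_tree",
]
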