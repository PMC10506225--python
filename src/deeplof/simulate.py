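"""Synthetic gene tables with the statistical structure the model assumes.

Each simulated gene carries a feature vector, a latent relative LOF rate
eta drawn from a beta prior whose mean is a logistic-linear function of the
(standardized) features, an expected LOF count n drawn from a clipped
log-normal, and an observed count y ~ Poisson(eta * n).  Continuous features
are a mix of symmetric Gaussians and exponentiated Gaussians (right-skewed,
nonnegative, flagged for log transformation); binary features are Bernoulli.
Missing values are inserted into continuous columns at a configurable rate.

Defaults mirror a gnomAD-style constraint table: 19,197 genes, 12 continuous
plus 6 binary features, expected counts with median ~5 spanning roughly
0.1-200 so that short genes (n <= 10) are well represented.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .bayes import GeneRecord
from .features import FeatureSpec

__all__ = [
    "SimConfig",
    "SimTruth",
    "generate_features",
    "generate_genes",
    "label_essential",
    "simulate_gene_table",
    "make_interval_fixture",
]


@dataclass(frozen=True)
class SimConfig:
    """Generative settings for one synthetic gene table."""

    G: int = 19197
    F_cont: int = 12
    F_bin: int = 6
    missing_rate: float = 0.05
    true_w_mu: np.ndarray | None = None  # length F_cont + F_bin; drawn if None
    true_b_mu: float = 0.0
    kappa_value: float = 5.0
    true_w_kappa: np.ndarray | None = None  # optional feature-linked concentration
    n_median: float = 5.0
    n_log_sd: float = 1.5
    n_clip: tuple[float, float] = (0.1, 200.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.G < 10:
            raise ValueError("need at least 10 genes")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing rate must lie in [0, 1)")
        if self.kappa_value <= 0 or self.n_median <= 0 or self.n_log_sd <= 0:
            raise ValueError("kappa and log-normal parameters must be positive")
        for name in ("true_w_mu", "true_w_kappa"):
            v = getattr(self, name)
            if v is not None:
                object.__setattr__(self, name, np.asarray(v, dtype=float))

    @property
    def F(self) -> int:
        return self.F_cont + self.F_bin


@dataclass
class SimTruth:
    """Ground truth of one simulation: latent rates and generative weights."""

    gene_ids: np.ndarray
    eta: np.ndarray
    mu: np.ndarray
    kappa: np.ndarray
    w_mu: np.ndarray
    b_mu: float


def generate_features(config: SimConfig) -> tuple[pd.DataFrame, list[FeatureSpec]]:
    """Raw feature table (with missingness) plus the matching feature specs.

    Half of the continuous columns (rounded up) are exponentiated Gaussians:
    right-skewed, nonnegative and flagged ``log_transform``; the rest are
    plain Gaussians.  Binary columns are Bernoulli with inclusion
    probabilities spread over 0.05-0.5, mimicking curated gene-set
    memberships.
    """
    rng = np.random.default_rng(config.seed)
    cols: dict[str, np.ndarray] = {}
    specs: list[FeatureSpec] = []
    n_skew = (config.F_cont + 1) // 2
    for j in range(config.F_cont):
        if j < n_skew:
            x = np.exp(rng.normal(0.0, 1.0, size=config.G))
            spec = FeatureSpec(f"cont_{j}", "continuous", log_transform=True)
        else:
            x = rng.normal(0.0, 1.0, size=config.G)
            spec = FeatureSpec(f"cont_{j}", "continuous", log_transform=False)
        if config.missing_rate > 0:
            x = x.copy()
            x[rng.random(config.G) < config.missing_rate] = np.nan
        cols[spec.name] = x
        specs.append(spec)
    for j in range(config.F_bin):
        p = 0.05 + 0.45 * (j / max(config.F_bin - 1, 1))
        cols[f"bin_{j}"] = (rng.random(config.G) < p).astype(float)
        specs.append(FeatureSpec(f"bin_{j}", "binary"))
    table = pd.DataFrame(cols)
    table.insert(0, "gene_id", [f"g{i:06d}" for i in range(config.G)])
    return table, specs


def generate_genes(
    X: np.ndarray, config: SimConfig, gene_ids=None, mu_override=None
) -> tuple[list[GeneRecord], SimTruth]:
    """Draw (eta, n, y) per gene from the beta-Poisson generative model.

    ``X`` must be the preprocessed (standardized, imputed) feature matrix, so
    the logistic-linear map for the prior mean acts on the same scale the
    model sees.  All draws come from one generator seeded by ``config.seed``.
    ``mu_override`` replaces the logistic-linear prior mean with an arbitrary
    per-gene array in (0, 1), e.g. a nonlinear function of the features when
    stress-testing model selection.
    """
    X = np.asarray(X, dtype=float)
    G = X.shape[0]
    rng = np.random.default_rng(config.seed + 1)
    w = config.true_w_mu
    if w is None:
        w = rng.normal(0.0, 0.5, size=X.shape[1])
    w = np.asarray(w, dtype=float)
    if w.size != X.shape[1]:
        raise ValueError(f"true_w_mu has length {w.size}, expected {X.shape[1]}")
    if mu_override is not None:
        mu = np.asarray(mu_override, dtype=float)
        if mu.shape != (G,) or np.any(mu <= 0) or np.any(mu >= 1):
            raise ValueError("mu_override must be a length-G array strictly inside (0, 1)")
    else:
        mu = expit(X @ w + config.true_b_mu)
    if config.true_w_kappa is not None:
        wk = np.asarray(config.true_w_kappa, dtype=float)
        if wk.size != X.shape[1]:
            raise ValueError(f"true_w_kappa has length {wk.size}, expected {X.shape[1]}")
        kappa = np.exp(X @ wk + np.log(config.kappa_value))
    else:
        kappa = np.full(G, config.kappa_value)
    eta = rng.beta(mu * kappa, (1.0 - mu) * kappa)
    eta = np.clip(eta, 1e-12, 1.0 - 1e-12)
    n = np.exp(rng.normal(np.log(config.n_median), config.n_log_sd, size=G))
    n = np.clip(n, *config.n_clip)
    y = rng.poisson(eta * n)
    if gene_ids is None:
        gene_ids = np.array([f"g{i:06d}" for i in range(G)])
    else:
        gene_ids = np.asarray(gene_ids)
    records = [
        GeneRecord(gene_id=str(gene_ids[i]), x=X[i], y=int(y[i]), n=float(n[i]))
        for i in range(G)
    ]
    truth = SimTruth(
        gene_ids=gene_ids, eta=eta, mu=mu, kappa=kappa, w_mu=w, b_mu=config.true_b_mu
    )
    return records, truth


def label_essential(truth: SimTruth, quantile: float = 0.1) -> pd.Series:
    """Label the lowest-eta fraction of genes essential, the rest nonessential.

    Stands in for curated essential-gene sets when benchmarking score
    rankings on synthetic data.
    """
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must lie strictly in (0, 1)")
    cutoff = np.quantile(truth.eta, quantile)
    labels = np.where(truth.eta <= cutoff, "essential", "nonessential")
    return pd.Series(labels, index=[str(g) for g in truth.gene_ids], name="label")


def simulate_gene_table(config: SimConfig):
    """Full pipeline convenience: features -> preprocess -> records.

    Returns ``(raw_table, specs, records, truth)`` where ``raw_table`` also
    carries ``obs_lof`` and ``exp_lof`` columns, i.e. exactly the TSV layout
    the readers and the CLI consume.
    """
    from .features import build_feature_matrix

    raw, specs = generate_features(config)
    matrix = build_feature_matrix(raw, specs)
    records, truth = generate_genes(matrix.values, config, gene_ids=raw["gene_id"].to_numpy())
    table = raw.copy()
    table.insert(1, "obs_lof", [r.y for r in records])
    table.insert(2, "exp_lof", [r.n for r in records])
    return table, specs, records, truth


def make_interval_fixture(
    n_genes: int = 200,
    n_deletions: int = 100,
    chrom: str = "chrS",
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Toy gene spans and deletion spans on one synthetic chromosome.

    Genes are laid out left to right with random lengths and gaps; deletions
    are random intervals over the same coordinate range.  Both tables use
    0-based half-open (BED) coordinates.
    """
    rng = np.random.default_rng(seed)
    starts = np.cumsum(rng.integers(1_000, 20_000, size=n_genes))
    lengths = rng.integers(500, 50_000, size=n_genes)
    genes = pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": starts + lengths,
            "name": [f"g{i:06d}" for i in range(n_genes)],
        }
    )
    span_end = int(genes["end"].max())
    del_start = rng.integers(0, span_end, size=n_deletions)
    del_len = rng.integers(1_000, 100_000, size=n_deletions)
    deletions = pd.DataFrame(
        {
            "chrom": chrom,
            "start": del_start,
            "end": del_start + del_len,
            "name": [f"del{i:04d}" for i in range(n_deletions)],
        }
    )
    return genes, deletions
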