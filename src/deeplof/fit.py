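"""Model fitting: train/validation split, mini-batch Adam, grid search, scoring.

The training objective is the mean negative log marginal likelihood of the
beta-Poisson model over a mini-batch, plus an L2 penalty on weights (biases
excluded).  The marginal likelihood integral is approximated by a fixed
midpoint grid, so differentiating through the grid sum gives the exact
gradient of the discretized objective.  For one gene with prior (mu, kappa),

    d log P / d mu    = kappa * (E[log eta] - E[log(1-eta)] - psi(a) + psi(b))
    d log P / d kappa = mu * E[log eta] + (1-mu) * E[log(1-eta)]
                        - mu * psi(a) - (1-mu) * psi(b) + psi(kappa)

where a = mu*kappa, b = (1-mu)*kappa, psi is the digamma function and the
expectations are under the (grid-discretized) posterior of eta.  These
derivatives are chained through the link functions mu = logistic(s_m),
kappa = exp(s_k) and then through the prior network by ordinary
backpropagation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import digamma, gammaln

from .bayes import GeneRecord, QuadratureGrid, make_quadrature_grid
from .network import PriorNetworkParams, forward_batch, params_from_arrays, params_to_arrays
from .optim import Adam

__all__ = [
    "TrainConfig",
    "FitResult",
    "GeneDataset",
    "split_indices",
    "split_train_validation",
    "loss_and_grad",
    "train_model",
    "grid_search",
    "score_genes",
]

_VAL_CHUNK = 2048


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters and bookkeeping for one training run."""

    variant: str = "linear"  # "linear" | "nonlinear"
    learning_rate: float = 1e-3
    l2_penalty: float = 0.0
    hidden_units: int | None = None
    dropout_rate: float = 0.5
    batch_size: int = 64
    max_epochs: int = 1000
    patience: int = 10
    grid_K: int = 4096
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.l2_penalty < 0:
            raise ValueError("L2 penalty must be nonnegative")
        if self.batch_size < 1 or self.patience < 1 or self.max_epochs < 1:
            raise ValueError("batch size, patience and max epochs must be positive")
        if self.variant == "nonlinear" and not self.hidden_units:
            raise ValueError("nonlinear variant requires hidden_units")


@dataclass
class FitResult:
    """Fitted parameters plus per-epoch loss histories."""

    params: PriorNetworkParams
    train_loss_history: list[float]
    val_loss_history: list[float]
    best_epoch: int
    best_val_loss: float
    config: TrainConfig | None = None


@dataclass
class GeneDataset:
    """Aligned arrays for a set of genes (columnar form of GeneRecord lists)."""

    gene_ids: np.ndarray
    X: np.ndarray
    y: np.ndarray
    n: np.ndarray

    @classmethod
    def from_records(cls, records: list[GeneRecord]) -> "GeneDataset":
        if not records:
            raise ValueError("empty record list")
        return cls(
            gene_ids=np.array([r.gene_id for r in records]),
            X=np.vstack([r.x for r in records]) if records[0].x.size else np.empty((len(records), 0)),
            y=np.array([r.y for r in records], dtype=float),
            n=np.array([r.n for r in records], dtype=float),
        )

    def subset(self, idx: np.ndarray) -> "GeneDataset":
        return GeneDataset(self.gene_ids[idx], self.X[idx], self.y[idx], self.n[idx])

    def __len__(self) -> int:
        return self.y.size


def _as_dataset(data) -> GeneDataset:
    if isinstance(data, GeneDataset):
        return data
    return GeneDataset.from_records(list(data))


def split_indices(G: int, train_fraction: float, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Seeded disjoint exhaustive train/validation index split.

    The training set receives round(G * train_fraction) genes (banker's
    rounding via numpy), the validation set the remainder; both must be
    nonempty.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train fraction must lie strictly in (0, 1)")
    if G < 2:
        raise ValueError("need at least 2 genes to split")
    n_train = int(np.rint(G * train_fraction))
    n_train = min(max(n_train, 1), G - 1)
    perm = np.random.default_rng(seed).permutation(G)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def split_train_validation(records, train_fraction: float = 0.8, seed: int = 0):
    """Split a list of gene records into disjoint train/validation lists."""
    records = list(records)
    tr, va = split_indices(len(records), train_fraction, seed)
    return [records[i] for i in tr], [records[i] for i in va]


def _marginal_and_grad(y, n, mu, kappa, grid: QuadratureGrid):
    """log P(y|x,n) per gene and its derivatives w.r.t. mu and kappa."""
    eta = grid.midpoints[None, :]
    log_eta = np.log(grid.midpoints)[None, :]
    log_1m = np.log1p(-grid.midpoints)[None, :]
    a = (mu * kappa)[:, None]
    b = ((1.0 - mu) * kappa)[:, None]
    lj = (
        (a - 1.0) * log_eta
        + (b - 1.0) * log_1m
        - gammaln(a)
        - gammaln(b)
        + gammaln(kappa)[:, None]
    )
    rate = eta * n[:, None]
    lj += y[:, None] * np.log(rate) - rate - gammaln(y + 1.0)[:, None]
    m = lj.max(axis=1, keepdims=True)
    w = np.exp(lj - m)
    s = w.sum(axis=1)
    log_marg = m[:, 0] + np.log(s) + grid.log_weight
    r = w / s[:, None]  # grid-posterior weights
    e_log_eta = r @ np.log(grid.midpoints)
    e_log_1m = r @ np.log1p(-grid.midpoints)
    psi_a = digamma(mu * kappa)
    psi_b = digamma((1.0 - mu) * kappa)
    d_mu = kappa * (e_log_eta - e_log_1m - psi_a + psi_b)
    d_kappa = (
        mu * e_log_eta
        + (1.0 - mu) * e_log_1m
        - mu * psi_a
        - (1.0 - mu) * psi_b
        + digamma(kappa)
    )
    return log_marg, d_mu, d_kappa


def loss_and_grad(
    params: PriorNetworkParams,
    X: np.ndarray,
    y: np.ndarray,
    n: np.ndarray,
    grid: QuadratureGrid,
    l2_penalty: float = 0.0,
    training: bool = False,
    rng: np.random.Generator | None = None,
):
    """Penalized mean negative log marginal likelihood and its gradients.

    Returns ``(loss, grads)`` with ``grads`` keyed like
    :func:`deeplof.network.params_to_arrays` (weights and biases only).
    """
    B = y.size
    mu, kappa, cache = forward_batch(X, params, training=training, rng=rng)
    log_marg, d_mu, d_kappa = _marginal_and_grad(y, n, mu, kappa, grid)
    if not np.all(np.isfinite(log_marg)):
        raise FloatingPointError("non-finite log marginal likelihood in batch")
    weight_sq = float(np.sum(params.w_m**2) + np.sum(params.w_k**2))
    if params.variant == "nonlinear":
        weight_sq += float(np.sum(params.W_h**2))
    loss = float(-log_marg.mean()) + l2_penalty * weight_sq

    z = cache["z"]
    ds_m = -(d_mu * mu * (1.0 - mu)) / B  # d loss / d (w_m.z + b_m)
    ds_k = -(d_kappa * kappa) / B
    grads = {
        "w_m": z.T @ ds_m + 2.0 * l2_penalty * params.w_m,
        "b_m": float(ds_m.sum()),
        "w_k": z.T @ ds_k + 2.0 * l2_penalty * params.w_k,
        "b_k": float(ds_k.sum()),
    }
    if params.variant == "nonlinear":
        dz = np.outer(ds_m, params.w_m) + np.outer(ds_k, params.w_k)
        if "dropout_mask" in cache:
            dz = dz * cache["dropout_mask"]
        dpre = dz * cache["relu_mask"]
        grads["W_h"] = cache["X"].T @ dpre + 2.0 * l2_penalty * params.W_h
        grads["b_h"] = dpre.sum(axis=0)
    return loss, grads


def _data_loss(params: PriorNetworkParams, data: GeneDataset, grid: QuadratureGrid) -> float:
    """Unpenalized mean NLL with dropout disabled, chunked to bound memory."""
    total = 0.0
    for start in range(0, len(data), _VAL_CHUNK):
        sl = slice(start, start + _VAL_CHUNK)
        mu, kappa, _ = forward_batch(data.X[sl], params, training=False)
        log_marg, _, _ = _marginal_and_grad(data.y[sl], data.n[sl], mu, kappa, grid)
        total += float(-log_marg.sum())
    return total / len(data)


def _trainable(params: PriorNetworkParams) -> dict[str, np.ndarray]:
    arrays = params_to_arrays(params)
    return {k: np.asarray(v, dtype=float) for k, v in arrays.items() if k not in ("variant", "dropout_rate")}


def _rebuild(params: PriorNetworkParams, arrays: dict[str, np.ndarray]) -> PriorNetworkParams:
    full = params_to_arrays(params) | arrays
    return params_from_arrays(full)


def train_model(train, val, config: TrainConfig, init: PriorNetworkParams | None = None) -> FitResult:
    """Fit the prior network by mini-batch Adam with early stopping.

    Shuffling and dropout draw from a single generator seeded by
    ``config.seed``, so identical configs give identical loss histories.
    Training stops once the validation loss has failed to improve for
    ``config.patience`` consecutive epochs; the returned parameters are the
    ones from the best-validation epoch.
    """
    train = _as_dataset(train)
    val = _as_dataset(val)
    grid = make_quadrature_grid(config.grid_K)
    rng = np.random.default_rng(config.seed)
    if init is None:
        from .network import init_params

        init = init_params(
            F=train.X.shape[1],
            H=config.hidden_units if config.variant == "nonlinear" else None,
            seed=config.seed,
            dropout_rate=config.dropout_rate,
        )
    params = init
    optimizer = Adam(learning_rate=config.learning_rate)
    train_history: list[float] = []
    val_history: list[float] = []
    best_val = np.inf
    best_epoch = -1
    best_params = params
    stale = 0
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(train))
        epoch_losses = []
        for start in range(0, len(train), config.batch_size):
            idx = order[start : start + config.batch_size]
            try:
                loss, grads = loss_and_grad(
                    params,
                    train.X[idx],
                    train.y[idx],
                    train.n[idx],
                    grid,
                    l2_penalty=config.l2_penalty,
                    training=True,
                    rng=rng,
                )
            except FloatingPointError as err:
                raise RuntimeError(f"training diverged at epoch {epoch}: {err}") from err
            if not np.isfinite(loss):
                raise RuntimeError(f"training diverged at epoch {epoch}: non-finite loss")
            params = _rebuild(params, optimizer.step(_trainable(params), grads))
            epoch_losses.append(loss)
        train_history.append(float(np.mean(epoch_losses)))
        val_loss = _data_loss(params, val, grid)
        if not np.isfinite(val_loss):
            raise RuntimeError(f"training diverged at epoch {epoch}: non-finite validation loss")
        val_history.append(val_loss)
        if val_loss < best_val:
            best_val = val_loss
            best_epoch = epoch
            best_params = params
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break
    return FitResult(
        params=best_params,
        train_loss_history=train_history,
        val_loss_history=val_history,
        best_epoch=best_epoch,
        best_val_loss=float(best_val),
        config=config,
    )


def grid_search(
    train,
    val,
    base: TrainConfig,
    l2_grid=(0.0, 1e-2, 1e-3, 1e-4, 1e-5, 1e-6),
    lr_grid=(1e-3, 1e-4, 1e-5),
    hidden_grid=(64, 128, 256, 512, 1024),
) -> tuple[TrainConfig, FitResult, pd.DataFrame]:
    """Exhaustive Cartesian hyperparameter sweep on the validation loss.

    For the linear variant the hidden-unit grid is ignored.  Ties on the best
    validation loss are broken by smaller hidden size, then larger L2
    penalty, then declaration order, so the sweep is reproducible.
    """
    if not l2_grid or not lr_grid or (base.variant == "nonlinear" and not hidden_grid):
        raise ValueError("hyperparameter grids must be nonempty")
    train = _as_dataset(train)
    val = _as_dataset(val)
    hiddens = list(hidden_grid) if base.variant == "nonlinear" else [None]
    rows = []
    best_key = None
    best: tuple[TrainConfig, FitResult] | None = None
    for order, (h, l2, lr) in enumerate(itertools.product(hiddens, l2_grid, lr_grid)):
        config = replace(base, hidden_units=h, l2_penalty=l2, learning_rate=lr)
        result = train_model(train, val, config)
        rows.append(
            {
                "hidden_units": h,
                "l2_penalty": l2,
                "learning_rate": lr,
                "best_val_loss": result.best_val_loss,
                "best_epoch": result.best_epoch,
            }
        )
        key = (result.best_val_loss, h if h is not None else 0, -l2, order)
        if best_key is None or key < best_key:
            best_key = key
            best = (config, result)
    assert best is not None
    return best[0], best[1], pd.DataFrame(rows)


def score_genes(data, params: PriorNetworkParams, grid: QuadratureGrid) -> pd.DataFrame:
    """Posterior mean of eta and intolerance score for every gene.

    Deterministic: dropout is disabled.  Raises if any score is non-finite,
    naming the offending gene.
    """
    data = _as_dataset(data)
    means = np.empty(len(data))
    for start in range(0, len(data), _VAL_CHUNK):
        sl = slice(start, start + _VAL_CHUNK)
        mu, kappa, _ = forward_batch(data.X[sl], params, training=False)
        eta = grid.midpoints[None, :]
        a = (mu * kappa)[:, None]
        b = ((1.0 - mu) * kappa)[:, None]
        lj = (
            (a - 1.0) * np.log(eta)
            + (b - 1.0) * np.log1p(-eta)
            - gammaln(a)
            - gammaln(b)
            + gammaln(kappa)[:, None]
        )
        rate = eta * data.n[sl][:, None]
        lj += data.y[sl][:, None] * np.log(rate) - rate - gammaln(data.y[sl] + 1.0)[:, None]
        m = lj.max(axis=1, keepdims=True)
        w = np.exp(lj - m)
        means[sl] = (w @ grid.midpoints) / w.sum(axis=1)
    if not np.all(np.isfinite(means)):
        bad = data.gene_ids[~np.isfinite(means)]
        raise FloatingPointError(f"non-finite posterior mean for genes {list(bad)}")
    return pd.DataFrame(
        {
            "gene_id": data.gene_ids,
            "posterior_mean_eta": means,
            "deeplof_score": 1.0 - means,
        }
    )
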