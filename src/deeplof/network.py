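"""Prior network: maps gene features to the beta prior parameters (mu, kappa).

Two variants are supported.  The linear variant applies affine maps followed
by the link functions

    mu    = logistic(w_m . x + b_m)
    kappa = exp(w_k . x + b_k)

so the sign of each weight in ``w_m`` is directly interpretable; the
contribution score of feature j is -w_m[j] (positive = associated with LOF
intolerance, i.e. smaller eta).  The nonlinear variant inserts one hidden
layer z = Dropout(ReLU(W_h^T x + b_h)) before the same two heads.  Dropout
uses the inverted convention (activations scaled by 1/(1-p) at train time),
so inference needs no rescaling and is deterministic.

A model with zero features (F = 0) degenerates to the intercept-only "flat"
prior shared by all genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .bayes import BetaParams

__all__ = [
    "PriorNetworkParams",
    "ContributionScores",
    "init_params",
    "linear_prior_forward",
    "nonlinear_prior_forward",
    "prior_forward",
    "forward_batch",
    "contribution_scores",
    "params_to_arrays",
    "params_from_arrays",
]


@dataclass(frozen=True)
class PriorNetworkParams:
    """Weights and biases of the linear or one-hidden-layer prior network."""

    variant: str  # "linear" | "nonlinear"
    w_m: np.ndarray  # (F,) or (H,)
    b_m: float
    w_k: np.ndarray  # (F,) or (H,)
    b_k: float
    W_h: np.ndarray | None = None  # (F, H), nonlinear only
    b_h: np.ndarray | None = None  # (H,), nonlinear only
    dropout_rate: float = 0.5

    def __post_init__(self) -> None:
        if self.variant not in ("linear", "nonlinear"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        for name in ("w_m", "w_k"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.variant == "nonlinear":
            if self.W_h is None or self.b_h is None:
                raise ValueError("nonlinear variant requires W_h and b_h")
            object.__setattr__(self, "W_h", np.asarray(self.W_h, dtype=float))
            object.__setattr__(self, "b_h", np.asarray(self.b_h, dtype=float))
            H = self.W_h.shape[1]
            if self.b_h.shape != (H,) or self.w_m.shape != (H,) or self.w_k.shape != (H,):
                raise ValueError("inconsistent hidden-layer shapes")
        if self.w_m.shape != self.w_k.shape:
            raise ValueError("mu and kappa heads must have matching input size")
        for arr in (self.w_m, self.w_k, np.asarray([self.b_m, self.b_k])):
            if not np.all(np.isfinite(arr)):
                raise ValueError("network parameters must be finite")

    @property
    def n_features(self) -> int:
        return self.W_h.shape[0] if self.variant == "nonlinear" else self.w_m.size

    @property
    def n_hidden(self) -> int | None:
        return self.W_h.shape[1] if self.variant == "nonlinear" else None


@dataclass(frozen=True)
class ContributionScores:
    """Per-feature association with LOF intolerance from the linear model."""

    names: tuple[str, ...]
    values: np.ndarray

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, map(float, self.values)))


def init_params(
    F: int,
    H: int | None = None,
    seed: int = 0,
    dropout_rate: float = 0.5,
) -> PriorNetworkParams:
    """Glorot-uniform weights and zero biases, reproducible from ``seed``.

    With zero biases and centered features the initial prior mean starts near
    logistic(0) = 0.5 and the concentration near exp(0) = 1.
    """
    if F < 0:
        raise ValueError("feature count must be nonnegative")
    rng = np.random.default_rng(seed)

    def glorot(fan_in: int, fan_out: int, shape) -> np.ndarray:
        limit = np.sqrt(6.0 / (fan_in + fan_out)) if fan_in + fan_out > 0 else 0.0
        return rng.uniform(-limit, limit, size=shape)

    if H is None:
        return PriorNetworkParams(
            variant="linear",
            w_m=glorot(F, 1, (F,)),
            b_m=0.0,
            w_k=glorot(F, 1, (F,)),
            b_k=0.0,
            dropout_rate=dropout_rate,
        )
    if H < 1:
        raise ValueError("hidden unit count must be at least 1")
    return PriorNetworkParams(
        variant="nonlinear",
        W_h=glorot(F, H, (F, H)),
        b_h=np.zeros(H),
        w_m=glorot(H, 1, (H,)),
        b_m=0.0,
        w_k=glorot(H, 1, (H,)),
        b_k=0.0,
        dropout_rate=dropout_rate,
    )


def _heads(z: np.ndarray, params: PriorNetworkParams) -> tuple[np.ndarray, np.ndarray]:
    # clip away from the boundary: expit saturates to exactly 0/1 in float64
    # beyond |s| ~ 37, where BetaParams would be invalid
    mu = np.clip(expit(z @ params.w_m + params.b_m), 1e-12, 1.0 - 1e-12)
    kappa = np.clip(np.exp(z @ params.w_k + params.b_k), 1e-12, 1e12)
    return mu, kappa


def linear_prior_forward(x: np.ndarray, params: PriorNetworkParams) -> BetaParams:
    """Affine + link map from one feature vector to BetaParams (linear variant)."""
    if params.variant != "linear":
        raise ValueError("linear_prior_forward requires a linear-variant parameter set")
    x = np.asarray(x, dtype=float)
    if x.shape != params.w_m.shape:
        raise ValueError(f"feature vector of length {x.size} does not match F={params.w_m.size}")
    mu, kappa = _heads(x[None, :], params)
    return BetaParams(mu=float(mu[0]), kappa=float(kappa[0]))


def nonlinear_prior_forward(
    x: np.ndarray,
    params: PriorNetworkParams,
    training: bool = False,
    rng_seed: int = 0,
) -> BetaParams:
    """One-hidden-layer map from one feature vector to BetaParams.

    With ``training=False`` the map is deterministic (dropout disabled).  With
    ``training=True`` dropout is applied with the inverted-scaling convention,
    reproducibly under ``rng_seed``.
    """
    if params.variant != "nonlinear":
        raise ValueError("nonlinear_prior_forward requires a nonlinear-variant parameter set")
    x = np.asarray(x, dtype=float)
    if x.shape != (params.W_h.shape[0],):
        raise ValueError(
            f"feature vector of length {x.size} does not match F={params.W_h.shape[0]}"
        )
    rng = np.random.default_rng(rng_seed) if training else None
    mu, kappa, _ = forward_batch(x[None, :], params, training=training, rng=rng)
    return BetaParams(mu=float(mu[0]), kappa=float(kappa[0]))


def prior_forward(x: np.ndarray, params: PriorNetworkParams) -> BetaParams:
    """Deterministic forward pass dispatching on the parameter variant."""
    if params.variant == "linear":
        return linear_prior_forward(x, params)
    return nonlinear_prior_forward(x, params, training=False)


def forward_batch(
    X: np.ndarray,
    params: PriorNetworkParams,
    training: bool = False,
    rng: np.random.Generator | None = None,
):
    """Vectorized forward pass over a (B, F) feature matrix.

    Returns (mu, kappa, cache); the cache holds the intermediates needed by
    the backward pass in :mod:`deeplof.fit`.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != params.n_features:
        raise ValueError(f"feature matrix shape {X.shape} does not match F={params.n_features}")
    cache: dict[str, np.ndarray] = {"X": X}
    if params.variant == "linear":
        z = X
    else:
        pre = X @ params.W_h + params.b_h
        relu_mask = pre > 0
        z = np.where(relu_mask, pre, 0.0)
        cache["relu_mask"] = relu_mask
        if training and params.dropout_rate > 0.0:
            if rng is None:
                raise ValueError("training-mode dropout requires an rng")
            keep = 1.0 - params.dropout_rate
            mask = (rng.random(z.shape) < keep) / keep
            z = z * mask
            cache["dropout_mask"] = mask
    cache["z"] = z
    mu, kappa = _heads(z, params)
    cache["mu"] = mu
    cache["kappa"] = kappa
    return mu, kappa, cache


def contribution_scores(
    params: PriorNetworkParams, feature_names: list[str] | None = None
) -> ContributionScores:
    """Per-feature contribution scores -w_m[j] of the fitted linear model.

    Positive values mark features associated with LOF intolerance.  Undefined
    for the nonlinear variant.
    """
    if params.variant != "linear":
        raise ValueError("contribution scores are defined only for the linear variant")
    values = -params.w_m
    if feature_names is None:
        feature_names = [f"feature_{j}" for j in range(values.size)]
    if len(feature_names) != values.size:
        raise ValueError("feature name list does not match weight vector length")
    return ContributionScores(names=tuple(feature_names), values=values)


def params_to_arrays(params: PriorNetworkParams) -> dict:
    """Flatten parameters to a name -> array/scalar mapping for checkpoints."""
    out = {
        "variant": params.variant,
        "dropout_rate": params.dropout_rate,
        "w_m": params.w_m,
        "b_m": params.b_m,
        "w_k": params.w_k,
        "b_k": params.b_k,
    }
    if params.variant == "nonlinear":
        out["W_h"] = params.W_h
        out["b_h"] = params.b_h
    return out


def params_from_arrays(arrays: dict) -> PriorNetworkParams:
    """Inverse of :func:`params_to_arrays`."""
    return PriorNetworkParams(
        variant=arrays["variant"],
        w_m=np.asarray(arrays["w_m"], dtype=float),
        b_m=float(arrays["b_m"]),
        w_k=np.asarray(arrays["w_k"], dtype=float),
        b_k=float(arrays["b_k"]),
        W_h=np.asarray(arrays["W_h"], dtype=float) if "W_h" in arrays else None,
        b_h=np.asarray(arrays["b_h"], dtype=float) if "b_h" in arrays else None,
        dropout_rate=float(arrays.get("dropout_rate", 0.5)),
    )
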