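"""Model/Results interface to the beta-Poisson intolerance model.

``DeepLOFModel`` holds the data (observed counts y, expected counts n, and a
preprocessed feature matrix X) and fitting choices; ``fit`` and
``fit_grid_search`` return a ``DeepLOFResults`` carrying the trained prior
network, loss histories, per-gene posterior summaries and, for the linear
variant, per-feature contribution scores.

Typical use::

    specs = [FeatureSpec(...), ...]
    model = DeepLOFModel.from_dataframe(table, specs, variant="linear")
    res = model.fit(seed=1)
    print(res.summary())
    scores = res.score_table()          # gene_id, posterior_mean_eta, deeplof_score
    contrib = res.contribution_scores() # pandas Series, positive = intolerance-linked
"""

from __future__ import annotations



import numpy as np
import pandas as pd

from .bayes import make_quadrature_grid
from .features import FeatureSpec, build_feature_matrix
from .fit import (
    FitResult,
    GeneDataset,
    TrainConfig,
    grid_search,
    score_genes,
    split_indices,
    train_model,
)
from .network import contribution_scores as _contribution_scores

__all__ = ["DeepLOFModel", "DeepLOFResults"]


class DeepLOFModel:
    """Beta-Poisson LOF-intolerance model with a feature-parameterized prior.

    Parameters
    ----------
    y, n : arrays
        Observed and expected LOF counts per gene.
    X : array of shape (G, F), optional
        Preprocessed (standardized, imputed) feature matrix.  Omit, or pass a
        zero-column array, for the flat model whose prior is shared by all
        genes.
    gene_ids, feature_names : sequences, optional
        Identifiers; generated when omitted.
    variant : {"linear", "nonlinear", "flat"}
        Prior network form.  "flat" drops the features entirely.
    quadrature_k : int
        Number of midpoint abscissae for the marginal-likelihood integral.
    """

    def __init__(
        self,
        y,
        n,
        X=None,
        gene_ids=None,
        feature_names=None,
        variant: str = "linear",
        quadrature_k: int = 4096,
    ) -> None:
        y = np.asarray(y, dtype=float)
        n = np.asarray(n, dtype=float)
        if y.size != n.size:
            raise ValueError("y and n must be aligned")
        if np.any(y < 0) or np.any(y != np.round(y)):
            raise ValueError("observed counts must be nonnegative integers")
        if np.any(~np.isfinite(n)) or np.any(n <= 0):
            raise ValueError("expected counts must be positive and finite")
        if variant not in ("linear", "nonlinear", "flat"):
            raise ValueError(f"unknown variant {variant!r}")
        if variant == "flat" or X is None:
            X = np.empty((y.size, 0))
            variant_net = "linear"
            feature_names = []
        else:
            X = np.asarray(X, dtype=float)
            variant_net = variant
        if X.shape[0] != y.size:
            raise ValueError("feature matrix and counts must be aligned")
        if gene_ids is None:
            gene_ids = [f"g{i:06d}" for i in range(y.size)]
        if feature_names is None:
            feature_names = [f"feature_{j}" for j in range(X.shape[1])]
        self.variant = variant
        self._net_variant = variant_net
        self.feature_names = list(feature_names)
        self.quadrature_k = quadrature_k
        self.data = GeneDataset(
            gene_ids=np.asarray([str(g) for g in gene_ids]), X=X, y=y, n=n
        )

    @classmethod
    def from_dataframe(
        cls,
        table: pd.DataFrame,
        specs: list[FeatureSpec],
        variant: str = "linear",
        quadrature_k: int = 4096,
    ) -> "DeepLOFModel":
        """Build from a raw gene table (gene_id, obs_lof, exp_lof, features).

        Runs the full preprocessing pipeline (log transform, standardization,
        mean imputation) on the spec'd feature columns; the fitted transform
        state is kept on the model as ``feature_state``.
        """
        matrix = build_feature_matrix(table, specs) if specs else None
        model = cls(
            y=table["obs_lof"].to_numpy(),
            n=table["exp_lof"].to_numpy(),
            X=matrix.values if matrix is not None else None,
            gene_ids=table["gene_id"].to_numpy() if "gene_id" in table else None,
            feature_names=matrix.feature_names if matrix is not None else None,
            variant=variant if specs else "flat",
            quadrature_k=quadrature_k,
        )
        model.feature_state = matrix.transform_state if matrix is not None else {}
        return model

    @property
    def n_genes(self) -> int:
        return len(self.data)

    @property
    def n_features(self) -> int:
        return self.data.X.shape[1]

    def _config(self, **kwargs) -> TrainConfig:
        kwargs.setdefault("grid_K", self.quadrature_k)
        return TrainConfig(variant=self._net_variant, **kwargs)

    def fit(
        self,
        learning_rate: float = 1e-3,
        l2_penalty: float = 0.0,
        hidden_units: int | None = None,
        dropout_rate: float = 0.5,
        batch_size: int = 64,
        max_epochs: int = 1000,
        patience: int = 10,
        train_fraction: float = 0.8,
        seed: int = 0,
    ) -> "DeepLOFResults":
        """Fit with one hyperparameter setting; returns a results object."""
        config = self._config(
            learning_rate=learning_rate,
            l2_penalty=l2_penalty,
            hidden_units=hidden_units if self._net_variant == "nonlinear" else None,
            dropout_rate=dropout_rate,
            batch_size=batch_size,
            max_epochs=max_epochs,
            patience=patience,
            seed=seed,
        )
        tr, va = split_indices(self.n_genes, train_fraction, seed)
        result = train_model(self.data.subset(tr), self.data.subset(va), config)
        return DeepLOFResults(self, result)

    def fit_grid_search(
        self,
        l2_grid=(0.0, 1e-2, 1e-3, 1e-4, 1e-5, 1e-6),
        lr_grid=(1e-3, 1e-4, 1e-5),
        hidden_grid=(64, 128, 256, 512, 1024),
        train_fraction: float = 0.8,
        seed: int = 0,
        **config_kwargs,
    ) -> "DeepLOFResults":
        """Exhaustive hyperparameter sweep selected on validation loss."""
        base = self._config(seed=seed, **config_kwargs)
        tr, va = split_indices(self.n_genes, train_fraction, seed)
        config, result, table = grid_search(
            self.data.subset(tr),
            self.data.subset(va),
            base,
            l2_grid=l2_grid,
            lr_grid=lr_grid,
            hidden_grid=hidden_grid,
        )
        res = DeepLOFResults(self, result)
        res.search_table = table
        return res


class DeepLOFResults:
    """Fitted prior network plus posterior summaries and diagnostics."""

    def __init__(self, model: DeepLOFModel, fit_result: FitResult) -> None:
        self.model = model
        self.fit_result = fit_result
        self.params = fit_result.params
        self.search_table: pd.DataFrame | None = None
        self._scores: pd.DataFrame | None = None

    @property
    def best_val_loss(self) -> float:
        return self.fit_result.best_val_loss

    @property
    def best_epoch(self) -> int:
        return self.fit_result.best_epoch

    def score_table(self) -> pd.DataFrame:
        """Per-gene posterior mean of eta and intolerance score 1 - E[eta]."""
        if self._scores is None:
            grid = make_quadrature_grid(self.model.quadrature_k)
            self._scores = score_genes(self.model.data, self.params, grid)
        return self._scores

    @property
    def posterior_mean_eta(self) -> np.ndarray:
        return self.score_table()["posterior_mean_eta"].to_numpy()

    @property
    def scores(self) -> np.ndarray:
        return self.score_table()["deeplof_score"].to_numpy()

    def contribution_scores(self) -> pd.Series:
        """Per-feature contribution scores -w_mu (linear variant only)."""
        cs = _contribution_scores(self.params, self.model.feature_names)
        return pd.Series(cs.as_dict(), name="contribution_score")

    def summary(self) -> str:
        """Human-readable fit summary in the style of statsmodels results."""
        fr = self.fit_result
        lines = [
            "DeepLOF model results",
            "=" * 54,
            f"{'Variant:':<28}{self.model.variant}",
            f"{'Genes:':<28}{self.model.n_genes}",
            f"{'Features:':<28}{self.model.n_features}",
            f"{'Quadrature points:':<28}{self.model.quadrature_k}",
            f"{'Epochs run:':<28}{len(fr.val_loss_history)}",
            f"{'Best epoch:':<28}{fr.best_epoch}",
            f"{'Best validation loss:':<28}{fr.best_val_loss:.5f}",
        ]
        if self.params.variant == "linear" and self.model.n_features:
            lines += ["-" * 54, f"{'feature':<32}{'contribution':>12}"]
            for name, value in self.contribution_scores().items():
                lines.append(f"{name:<32}{value:>12.4f}")
        lines.append("=" * 54)
        return "\n".join(lines)

    def plot_loss(self, ax=None):
        """Training/validation loss curves; returns the matplotlib axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        fr = self.fit_result
        epochs = np.arange(len(fr.train_loss_history))
        ax.plot(epochs, fr.train_loss_history, label="train")
        ax.plot(epochs, fr.val_loss_history, label="validation")
        ax.axvline(fr.best_epoch, color="grey", ls=":", label="best epoch")
        ax.set_xlabel("epoch")
        ax.set_ylabel("mean negative log marginal likelihood")
        ax.legend()
        return ax

    def save(self, path) -> None:
        """Checkpoint the fitted parameters with model metadata (JSON)."""
        from .io import save_checkpoint

        save_checkpoint(
            path,
            self.params,
            meta={
                "variant": self.model.variant,
                "feature_names": self.model.feature_names,
                "quadrature_k": self.model.quadrature_k,
                "best_val_loss": self.fit_result.best_val_loss,
                "best_epoch": self.fit_result.best_epoch,
            },
        )
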