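import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from deeplof.bayes import BetaParams, make_quadrature_grid
from deeplof.features import build_feature_matrix
from deeplof.simulate import SimConfig, generate_features, generate_genes


@pytest.fixture(scope="session")
def grid4096():
    return make_quadrature_grid(4096)


@pytest.fixture(scope="session")
def uniform_prior():
    """Beta(1, 1): the conjugate test case with a truncated-gamma posterior."""
    return BetaParams(mu=0.5, kappa=2.0)


@pytest.fixture(scope="session")
def small_sim():
    """A 400-gene synthetic dataset with informative features, preprocessed."""
    config = SimConfig(
        G=400,
        F_cont=4,
        F_bin=2,
        missing_rate=0.05,
        kappa_value=5.0,
        true_w_mu=np.array([0.8, -0.5, 0.3, 0.0, 0.6, -0.4]),
        seed=11,
    )
    raw, specs = generate_features(config)
    matrix = build_feature_matrix(raw, specs)
    records, truth = generate_genes(
        matrix.values, config, gene_ids=raw["gene_id"].to_numpy()
    )
    return {
        "config": config,
        "raw": raw,
        "specs": specs,
        "matrix": matrix,
        "records": records,
        "truth": truth,
    }
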