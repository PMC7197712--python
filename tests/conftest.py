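import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from heartregen import sim
from heartregen.io import CountMatrix, ExpressionMatrix, TRANSGENE_FEATURES


def make_count_matrix(counts, feature_names=None, samples=None, barcodes=None):
    """Build a CountMatrix from a dense array for small fixtures."""
    counts = np.asarray(counts)
    n, p = counts.shape
    if feature_names is None:
        feature_names = [f"g{i}" for i in range(p)]
    from heartregen.io import classify_feature_names

    features = pd.DataFrame(
        {
            "name": list(feature_names),
            "feature_class": classify_feature_names(list(feature_names)),
        }
    )
    return CountMatrix(
        X=sp.csr_matrix(counts),
        barcodes=barcodes if barcodes is not None else [f"bc{i}" for i in range(n)],
        features=features,
        samples=samples,
    )


def lognorm_from_dense(values, feature_names=None, samples=None):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    if feature_names is None:
        feature_names = [f"g{i}" for i in range(p)]
    features = pd.DataFrame(
        {"name": list(feature_names), "feature_class": ["gene"] * p}
    )
    return ExpressionMatrix(
        X=sp.csr_matrix(values),
        barcodes=np.array([f"bc{i}" for i in range(n)], dtype=object),
        features=features,
        samples=np.asarray(samples, dtype=object)
        if samples is not None
        else np.full(n, "s1", dtype=object),
    )


@pytest.fixture(scope="session")
def small_dataset():
    """Three-sample study-like dataset, small enough for fast tests."""
    cfg = sim.default_config(n_genes=500, scale=0.1, seed=11)
    matrix, truth = sim.simulate_dataset(cfg)
    return cfg, matrix, truth


@pytest.fixture(scope="session")
def reporter_dataset():
    """Single sample with guaranteed (noiseless) reporter emission."""
    cfg = sim.default_config(n_genes=400, scale=0.08, seed=3)
    cfg.guaranteed_reporter_umi = True
    cfg.doublet_fraction = 0.0
    cfg.lowq_fraction = 0.0
    matrix, truth = sim.simulate_sample(cfg, "wt_3dpci")
    return cfg, matrix, truth
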