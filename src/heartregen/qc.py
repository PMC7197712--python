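"""Cell-level quality control.

The fixed filtering order is: (1) remove cells expressing fewer than
``min_genes`` features; (2) score and remove doublets; (3) drop genes with no
counts; (4) normalise each cell to a common total and log-transform.  Exact
bookkeeping (retained = passed - removed) holds at every step.

The doublet scorer is a simulated-doublet k-nearest-neighbour classifier
written here from scratch: synthetic doublets are formed by summing random
pairs of observed raw profiles, embedded together with the observed cells in a
normalise -> log -> HVG -> PCA space, and each observed cell is scored by the
fraction of simulated doublets among its nearest neighbours, calibrated by the
simulated-to-observed ratio so scores live in [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .io import CountMatrix, ExpressionMatrix


@dataclass
class QCConfig:
    """Quality-control parameters.

    ``doublet_threshold`` may be a single number or a per-sample mapping; the
    study's published per-sample cut-offs were 0.3, 0.27 and 0.38 for the
    uninjured wild-type, injured wild-type and injured mutant samples.
    """

    min_genes: int = 100
    doublet_threshold: "float | dict[str, float]" = 0.3
    doublet_sim_ratio: float = 2.0
    doublet_knn: int = 30
    doublet_n_pcs: int = 30
    expected_doublet_rate: float = 0.06
    target_sum: float = 10_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        thresholds = (
            self.doublet_threshold.values()
            if isinstance(self.doublet_threshold, dict)
            else [self.doublet_threshold]
        )
        for t in thresholds:
            if not 0.0 <= t <= 1.0:
                raise ValueError(f"doublet threshold {t} outside [0, 1]")
        if self.target_sum <= 0:
            raise ValueError("target_sum must be > 0")
        if self.doublet_sim_ratio <= 0:
            raise ValueError("doublet_sim_ratio must be > 0")
        if not 0.0 < self.expected_doublet_rate < 1.0:
            raise ValueError("expected_doublet_rate must be in (0, 1)")


def filter_low_gene_cells(
    matrix: CountMatrix, min_genes: int = 100
) -> tuple[CountMatrix, list[str]]:
    """Remove cells with strictly fewer than ``min_genes`` expressed features
    (count > 0).  A cell expressing exactly ``min_genes`` is retained."""
    if min_genes < 1:
        raise ValueError("min_genes must be >= 1")
    expressed = np.asarray((matrix.X > 0).sum(axis=1)).ravel()
    keep = expressed >= min_genes
    removed = list(matrix.barcodes[~keep])
    return matrix.subset_cells(keep), removed


def _lognorm_dense(counts: np.ndarray, target_sum: float) -> np.ndarray:
    totals = counts.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    return np.log1p(counts / totals * target_sum)


def score_doublets(matrix: CountMatrix, config: QCConfig | None = None) -> np.ndarray:
    """Simulated-doublet kNN score per cell, in [0, 1].

    With r simulated doublets per observed cell, k = ``doublet_knn`` and m
    simulated points among a cell's k nearest neighbours, the smoothed
    neighbour fraction q = (m+1)/(k+2) is rescaled by the simulated:observed
    ratio and calibrated against the ``expected_doublet_rate`` prior rho:

        score = (q * rho / r) / (1 - rho - q * (1 - rho - rho/r))

    the posterior probability that the cell is a doublet given its
    neighbourhood.  A cell whose neighbourhood mirrors the global mix scores
    ~rho; a cell surrounded by simulated doublets scores ~1.  Deterministic
    under a fixed config seed.
    """
    from .cluster import HVGConfig, select_hvgs  # local: avoids import cycle

    config = config or QCConfig()
    n = matrix.n_cells
    if n < 2:
        raise ValueError("need at least 2 cells to score doublets")
    k = config.doublet_knn
    if n < k + 1:
        raise ValueError(f"need more than doublet_knn={k} cells, got {n}")

    rng = np.random.default_rng(config.seed)
    X = matrix.X

    # restrict to features detected in the observed cells
    gene_tot = np.asarray(X.sum(axis=0)).ravel()
    X = X[:, gene_tot > 0].tocsr()

    obs = np.asarray(X.todense(), dtype=np.float64)
    obs_log = _lognorm_dense(obs, config.target_sum)

    hvg = select_hvgs(sp.csr_matrix(obs_log), HVGConfig())
    hvg_mask = hvg["highly_variable"].to_numpy()
    if hvg_mask.sum() < max(config.doublet_n_pcs, 2):
        hvg_mask = np.ones(obs_log.shape[1], dtype=bool)
    obs_log = obs_log[:, hvg_mask]

    mu = obs_log.mean(axis=0)
    sd = obs_log.std(axis=0)
    sd[sd == 0] = 1.0
    obs_std = (obs_log - mu) / sd

    n_pcs = min(config.doublet_n_pcs, n - 1, obs_std.shape[1])
    pca = PCA(n_components=n_pcs, svd_solver="full")
    obs_emb = pca.fit_transform(obs_std)

    n_sim = math.ceil(config.doublet_sim_ratio * n)
    pairs = rng.integers(0, n, size=(n_sim, 2))
    sim = obs[pairs[:, 0]] + obs[pairs[:, 1]]
    sim_std = (_lognorm_dense(sim, config.target_sum)[:, hvg_mask] - mu) / sd
    sim_emb = pca.transform(sim_std)

    combined = np.vstack([obs_emb, sim_emb])  # observed first
    nn = NearestNeighbors(n_neighbors=k + 1).fit(combined)
    _, idx = nn.kneighbors(obs_emb)
    # drop self where returned; otherwise drop the farthest neighbour
    neigh = np.empty((n, k), dtype=int)
    for i, row in enumerate(idx):
        row = row[row != i]
        neigh[i] = row[:k]
    m_sim = (neigh >= n).sum(axis=1)
    q = (m_sim + 1.0) / (k + 2.0)
    r = n_sim / n
    rho = config.expected_doublet_rate
    score = (q * rho / r) / (1.0 - rho - q * (1.0 - rho - rho / r))
    return np.clip(score, 0.0, 1.0)


def apply_doublet_filter(
    matrix: CountMatrix,
    scores: np.ndarray,
    threshold: "float | dict[str, float]",
) -> tuple[CountMatrix, list[str]]:
    """Remove cells whose doublet score strictly exceeds the threshold for
    their sample."""
    scores = np.asarray(scores, dtype=float)
    if scores.shape[0] != matrix.n_cells:
        raise ValueError(
            f"{scores.shape[0]} scores for {matrix.n_cells} cells"
        )
    if isinstance(threshold, dict):
        missing = set(matrix.samples) - set(threshold)
        if missing:
            raise KeyError(f"no doublet threshold for samples {sorted(missing)}")
        thr = np.array([threshold[s] for s in matrix.samples])
    else:
        thr = np.full(matrix.n_cells, float(threshold))
    keep = scores <= thr
    removed = list(matrix.barcodes[~keep])
    return matrix.subset_cells(keep), removed


def normalize_and_log(
    matrix: CountMatrix, target_sum: float = 10_000.0
) -> ExpressionMatrix:
    """Drop undetected genes, scale each cell to ``target_sum`` total counts,
    then apply log(1 + x) (natural log).

    After the transform, ``sum(expm1(row)) == target_sum`` for every cell.
    Cells with zero total counts must have been removed beforehand.
    """
    if target_sum <= 0:
        raise ValueError("target_sum must be > 0")
    totals = np.asarray(matrix.X.sum(axis=1)).ravel()
    if np.any(totals == 0):
        bad = matrix.barcodes[totals == 0][:5]
        raise ValueError(f"cells with zero total counts, e.g. {list(bad)}")
    gene_tot = np.asarray(matrix.X.sum(axis=0)).ravel()
    pruned = matrix.subset_features(gene_tot > 0)
    X = pruned.X.astype(np.float64).tocsr()
    scale = target_sum / totals
    X = sp.diags(scale) @ X
    X.data = np.log1p(X.data)
    return ExpressionMatrix(
        X=X.tocsr(),
        barcodes=pruned.barcodes,
        features=pruned.features,
        samples=pruned.samples,
    )


def qc_report(
    n_input: dict[str, int],
    passed: dict[str, int],
    doublets_removed: dict[str, int],
) -> "pd.DataFrame":
    """Per-sample bookkeeping table: barcodes in, low-gene removed, passed,
    doublets removed, retained (= passed - removed, an exact identity)."""
    import pandas as pd

    rows = []
    for s in n_input:
        rows.append(
            dict(
                sample=s,
                barcodes_in=n_input[s],
                low_gene_removed=n_input[s] - passed[s],
                passed=passed[s],
                doublets_removed=doublets_removed[s],
                retained=passed[s] - doublets_removed[s],
            )
        )
    return pd.DataFrame(rows)
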