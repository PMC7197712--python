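"""Dimensionality reduction and clustering.

The chain mirrors the study's analysis: select highly variable genes (HVGs) by
binned-dispersion z-scoring on log-normalised data, regress out total counts
and mitochondrial percentage, scale genes to zero mean and unit variance,
take the first 50 principal components, build a k=10 Euclidean nearest
neighbour graph, partition it with Louvain at a per-analysis resolution
(1 for all cells, 0.5 for cardiomyocytes, 0.6 / 0.7 for the double-positive
subsets) and lay it out with UMAP seeded for reproducibility.
"""

from __future__ import annotations

import random as _random
from dataclasses import dataclass, field

import igraph
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .io import CountMatrix, ExpressionMatrix
from .qc import normalize_and_log


@dataclass
class HVGConfig:
    """Dispersion-based HVG selection parameters (binned z-score method)."""

    min_mean: float = 0.0125
    max_mean: float = 4.0
    min_disp: float = 0.5
    n_bins: int = 20

    def __post_init__(self) -> None:
        if not self.min_mean < self.max_mean:
            raise ValueError("min_mean must be < max_mean")
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")


@dataclass
class ClusterConfig:
    n_pcs: int = 50
    knn_k: int = 10
    louvain_resolution: float = 1.0
    hvg: HVGConfig = field(default_factory=HVGConfig)
    target_sum: float = 10_000.0
    seed: int = 0


@dataclass
class KNNGraph:
    """k nearest neighbours (self excluded) plus the union-symmetrised
    adjacency used for community detection."""

    indices: np.ndarray  # (n, k) neighbour indices
    distances: np.ndarray  # (n, k) Euclidean distances
    adjacency: sp.csr_matrix  # symmetric, binary weights, zero diagonal

    @property
    def k(self) -> int:
        return self.indices.shape[1]


@dataclass
class ClusterResult:
    labels: np.ndarray  # per-cell cluster ids, contiguous from 0, size-ordered
    counts: pd.DataFrame  # cluster x sample cell counts
    embedding: np.ndarray | None  # (n, 2) UMAP coordinates
    hvg: pd.DataFrame | None = None
    pca_scores: np.ndarray | None = None

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0


# ---------------------------------------------------------------------------
# HVG selection
# ---------------------------------------------------------------------------

def select_hvgs(lognorm: "ExpressionMatrix | sp.spmatrix", config: HVGConfig | None = None) -> pd.DataFrame:
    """Per-gene mean/dispersion statistics and the HVG flag.

    Works on log-normalised input: counts are recovered with expm1, the
    per-gene mean mu and dispersion d = var/mu computed, genes binned into
    ``n_bins`` equal-width bins of log1p(mu), and d z-scored within each bin
    (bins with a single gene, or zero spread, get normalised dispersion 0).
    A gene is highly variable iff min_mean < log1p(mu) < max_mean and its
    normalised dispersion >= min_disp.
    """
    config = config or HVGConfig()
    X = lognorm.X if isinstance(lognorm, ExpressionMatrix) else sp.csr_matrix(lognorm)
    if X.shape[1] == 0 or X.nnz == 0:
        raise ValueError("all-zero matrix: nothing to select from")
    counts = X.copy()
    counts.data = np.expm1(counts.data)
    n = counts.shape[0]
    mean = np.asarray(counts.mean(axis=0)).ravel()
    sq = counts.copy()
    sq.data = sq.data**2
    ex2 = np.asarray(sq.mean(axis=0)).ravel()
    var = (ex2 - mean**2) * (n / max(n - 1, 1))  # ddof=1
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    log_mean = np.log1p(mean)

    edges = np.linspace(log_mean.min(), log_mean.max(), config.n_bins + 1)
    bins = np.clip(np.digitize(log_mean, edges[1:-1], right=False), 0, config.n_bins - 1)
    disp_norm = np.zeros_like(disp)
    for b in np.unique(bins):
        in_bin = bins == b
        if in_bin.sum() < 2:
            continue
        mu_b = disp[in_bin].mean()
        sd_b = disp[in_bin].std(ddof=1)
        if sd_b > 0:
            disp_norm[in_bin] = (disp[in_bin] - mu_b) / sd_b

    is_hvg = (
        (log_mean > config.min_mean)
        & (log_mean < config.max_mean)
        & (disp_norm >= config.min_disp)
    )
    names = (
        lognorm.feature_names
        if isinstance(lognorm, ExpressionMatrix)
        else np.array([f"g{i}" for i in range(X.shape[1])], dtype=object)
    )
    return pd.DataFrame(
        {
            "name": names,
            "mean": mean,
            "log1p_mean": log_mean,
            "dispersion": disp,
            "dispersion_norm": disp_norm,
            "highly_variable": is_hvg,
        }
    )


# ---------------------------------------------------------------------------
# Regression and scaling
# ---------------------------------------------------------------------------

def compute_covariates(raw: CountMatrix) -> np.ndarray:
    """Per-cell (total counts, % mitochondrial UMIs) from the raw matrix."""
    totals = np.asarray(raw.X.sum(axis=1)).ravel().astype(float)
    mito = raw.class_mask("mito")
    mito_tot = np.asarray(raw.X[:, mito].sum(axis=1)).ravel().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(totals > 0, 100.0 * mito_tot / totals, 0.0)
    return np.column_stack([totals, pct])


def regress_and_scale(
    lognorm: "ExpressionMatrix | np.ndarray | sp.spmatrix",
    covariates: np.ndarray,
    gene_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Residualise each gene against the covariates (with intercept) by least
    squares, then scale to zero mean and unit variance (ddof=1); genes with
    zero residual variance become all-zero columns.  Returns a dense array.

    ``gene_mask`` restricts the computation to a column subset (the operation
    is per-gene, so restricting commutes with selection).
    """
    X = lognorm.X if isinstance(lognorm, ExpressionMatrix) else lognorm
    X = np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X, dtype=float)
    if gene_mask is not None:
        X = X[:, np.asarray(gene_mask)]
    covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
    if covariates.shape[0] != X.shape[0]:
        raise ValueError(
            f"{covariates.shape[0]} covariate rows for {X.shape[0]} cells"
        )
    design = np.column_stack([np.ones(X.shape[0]), covariates])
    beta, *_ = np.linalg.lstsq(design, X, rcond=None)
    resid = X - design @ beta
    resid -= resid.mean(axis=0)  # exact zero-centering
    sd = resid.std(axis=0, ddof=1)
    out = np.divide(resid, sd, out=np.zeros_like(resid), where=sd > 0)
    return out


# ---------------------------------------------------------------------------
# PCA / kNN / Louvain / UMAP
# ---------------------------------------------------------------------------

def compute_pca(
    scaled: np.ndarray, n_pcs: int = 50, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PCA scores (cells x n_pcs), component loadings and explained
    variances, components ordered by non-increasing explained variance.

    Sign convention: each component is flipped so its largest-magnitude
    loading is positive, making scores reproducible across runs and solvers.
    """
    scaled = np.asarray(scaled, dtype=float)
    max_pcs = min(scaled.shape[0], scaled.shape[1])
    if n_pcs > max_pcs:
        raise ValueError(f"n_pcs={n_pcs} exceeds min(cells, genes)={max_pcs}")
    solver = "full" if max(scaled.shape) < 1000 else "randomized"
    pca = PCA(n_components=n_pcs, svd_solver=solver, random_state=seed)
    scores = pca.fit_transform(scaled)
    components = pca.components_.copy()
    for j in range(components.shape[0]):
        i_max = np.argmax(np.abs(components[j]))
        if components[j, i_max] < 0:
            components[j] *= -1
            scores[:, j] *= -1
    return scores, components, pca.explained_variance_.copy()


def knn_graph(scores: np.ndarray, k: int = 10) -> KNNGraph:
    """Euclidean k nearest neighbours of each cell (self excluded), plus the
    union-symmetrised binary adjacency."""
    scores = np.asarray(scores, dtype=float)
    n = scores.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= n:
        raise ValueError(f"k={k} must be < n cells={n}")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(scores)
    dist, idx = nn.kneighbors(scores)
    indices = np.empty((n, k), dtype=int)
    distances = np.empty((n, k), dtype=float)
    for i in range(n):
        row, d = idx[i], dist[i]
        keep = row != i
        indices[i] = row[keep][:k]
        distances[i] = d[keep][:k]
    rows = np.repeat(np.arange(n), k)
    adj = sp.coo_matrix(
        (np.ones(n * k), (rows, indices.ravel())), shape=(n, n)
    ).tocsr()
    adj = adj.maximum(adj.T)
    adj.setdiag(0)
    adj.eliminate_zeros()
    return KNNGraph(indices=indices, distances=distances, adjacency=adj)


def louvain_cluster(
    graph: "KNNGraph | sp.spmatrix", resolution: float = 1.0, seed: int = 0
) -> np.ndarray:
    """Louvain modularity clustering of the kNN graph at the given
    resolution; labels are relabelled in decreasing cluster size and the
    node-visit order is seeded, so results are deterministic."""
    adj = graph.adjacency if isinstance(graph, KNNGraph) else sp.csr_matrix(graph)
    n = adj.shape[0]
    if n == 0:
        raise ValueError("empty graph")
    coo = sp.triu(adj, k=1).tocoo()
    g = igraph.Graph(
        n=n, edges=list(zip(coo.row.tolist(), coo.col.tolist())), directed=False
    )
    weights = coo.data.tolist()
    state = _random.getstate()
    try:
        _random.seed(seed)  # python-igraph draws its randomness from `random`
        part = g.community_multilevel(weights=weights, resolution=resolution)
    finally:
        _random.setstate(state)
    labels = np.asarray(part.membership, dtype=int)
    # relabel by decreasing size, ties by first appearance
    ids, counts = np.unique(labels, return_counts=True)
    order = ids[np.lexsort((ids, -counts))]
    remap = {old: new for new, old in enumerate(order)}
    return np.array([remap[v] for v in labels], dtype=int)


def umap_embed(knn: KNNGraph, scores: np.ndarray, seed: int = 0) -> np.ndarray:
    """2-D UMAP layout computed from the package's own kNN graph (passed to
    the library as a precomputed neighbour set; self is neighbour 0)."""
    import umap  # deferred: heavy import

    scores = np.asarray(scores, dtype=float)
    n = scores.shape[0]
    if n == 0:
        raise ValueError("empty input")
    knn_indices = np.hstack([np.arange(n)[:, None], knn.indices])
    knn_dists = np.hstack([np.zeros((n, 1)), knn.distances])
    reducer = umap.UMAP(
        n_neighbors=knn_indices.shape[1],
        n_components=2,
        random_state=seed,
        precomputed_knn=(knn_indices, knn_dists),
    )
    emb = reducer.fit_transform(scores)
    if not np.all(np.isfinite(emb)):
        raise RuntimeError("non-finite UMAP coordinates")
    return np.asarray(emb, dtype=np.float64)


# ---------------------------------------------------------------------------
# End-to-end pipeline and subset re-clustering
# ---------------------------------------------------------------------------

def run_cluster_pipeline(
    raw: CountMatrix, config: ClusterConfig | None = None, with_umap: bool = True
) -> ClusterResult:
    """Full chain on QC-passed raw counts: normalise -> HVG -> regress/scale
    -> PCA -> kNN -> Louvain (-> UMAP)."""
    config = config or ClusterConfig()
    lognorm = normalize_and_log(raw, target_sum=config.target_sum)
    hvg = select_hvgs(lognorm, config.hvg)
    hvg_mask = hvg["highly_variable"].to_numpy()
    if hvg_mask.sum() < 2:
        raise ValueError("fewer than 2 highly variable genes")
    # raw matrix is re-aligned to the pruned gene space for covariates
    covs = compute_covariates(raw)
    scaled = regress_and_scale(lognorm, covs, gene_mask=hvg_mask)
    n_pcs = min(config.n_pcs, scaled.shape[0] - 1, scaled.shape[1])
    scores, _, _ = compute_pca(scaled, n_pcs=n_pcs, seed=config.seed)
    knn = knn_graph(scores, k=config.knn_k)
    labels = louvain_cluster(knn, resolution=config.louvain_resolution, seed=config.seed)
    counts = cluster_sample_table(labels, raw.samples)
    emb = umap_embed(knn, scores, seed=config.seed) if with_umap else None
    return ClusterResult(
        labels=labels, counts=counts, embedding=emb, hvg=hvg, pca_scores=scores
    )


def cluster_sample_table(labels: np.ndarray, samples: np.ndarray) -> pd.DataFrame:
    labels = np.asarray(labels)
    samples = np.asarray(samples, dtype=object).astype(str)
    if labels.shape[0] != samples.shape[0]:
        raise ValueError("labels and samples misaligned")
    tab = pd.crosstab(pd.Series(labels, name="cluster"), pd.Series(samples, name="sample"))
    return tab


def subset_and_recluster(
    raw: CountMatrix,
    mask: np.ndarray,
    config: ClusterConfig | None = None,
    with_umap: bool = True,
) -> ClusterResult:
    """Re-run the whole pipeline on a cell subset (e.g. cardiomyocytes at
    resolution 0.5, double-positive cells at 0.6/0.7) with the subset's own
    gene pruning and HVG selection."""
    config = config or ClusterConfig()
    mask = np.asarray(mask)
    n_sel = int(mask.sum()) if mask.dtype == bool else len(mask)
    if n_sel < config.knn_k + 1:
        raise ValueError(
            f"subset of {n_sel} cells too small for k={config.knn_k} neighbours"
        )
    return run_cluster_pipeline(raw.subset_cells(mask), config, with_umap=with_umap)
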