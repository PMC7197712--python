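"""Differential expression and GO enrichment.

Marker genes for a cluster are ranked by a variance-overestimating two-sample
t statistic against all remaining cells:

    t_g = (mu_group - mu_rest) / sqrt(s2_group/n_group + s2_rest/n_group)

i.e. the rest-group variance term is divided by the *group* size rather than
the rest size, deliberately inflating the denominator whenever the group is
the smaller side, which makes the test conservative.  The Welch-Satterthwaite
degrees of freedom are computed under the same substitution.  P values are
two-sided and Benjamini-Hochberg corrected.

GO enrichment is a one-sided hypergeometric test of each term's overlap with
the top-ranked genes, restricted to terms with more than five and fewer than
500 annotated genes in the universe, BH-corrected across the surviving terms.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .io import ExpressionMatrix


def _group_stats(X: sp.csr_matrix, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    n = int(mask.sum())
    sub = X[mask]
    mean = np.asarray(sub.mean(axis=0)).ravel()
    sq = sub.copy()
    sq.data = sq.data**2
    ex2 = np.asarray(sq.mean(axis=0)).ravel()
    var = np.maximum(ex2 - mean**2, 0.0) * (n / max(n - 1, 1))
    return mean, var, n


def overestimated_var_ttest(
    x_mean: np.ndarray,
    x_var: np.ndarray,
    n_group: int,
    y_mean: np.ndarray,
    y_var: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """The variance-overestimating t statistic and its two-sided p value.

    Both variance terms are divided by ``n_group`` and the same substitution
    enters the Welch-Satterthwaite degrees of freedom.  Genes with a zero
    denominator get t = 0, p = 1.
    """
    if n_group < 2:
        raise ValueError("group must have at least 2 cells")
    v1 = x_var / n_group
    v2 = y_var / n_group
    denom_sq = v1 + v2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom_sq > 0, (x_mean - y_mean) / np.sqrt(denom_sq), 0.0)
        df = np.where(
            denom_sq > 0,
            denom_sq**2 / (v1**2 / (n_group - 1) + v2**2 / (n_group - 1)),
            1.0,
        )
    p = np.where(denom_sq > 0, 2.0 * stats.t.sf(np.abs(t), df), 1.0)
    return t, p


def rank_genes(
    lognorm: ExpressionMatrix,
    labels: np.ndarray,
    group,
) -> pd.DataFrame:
    """Rank every gene for one cluster versus the rest.

    Returns a DataFrame sorted by descending t with columns: gene, mean_group,
    mean_rest, log2_fold_change (of back-transformed means, with a 1e-9
    floor), t, p, p_adj (BH).
    """
    labels = np.asarray(labels)
    if labels.shape[0] != lognorm.n_cells:
        raise ValueError("labels misaligned with cells")
    mask = labels == group
    n_group = int(mask.sum())
    n_rest = int((~mask).sum())
    if n_group < 2 or n_rest < 2:
        raise ValueError(
            f"group {group!r}: need >=2 cells on both sides, got "
            f"{n_group} vs {n_rest}"
        )
    X = lognorm.X.tocsr()
    mean_g, var_g, _ = _group_stats(X, mask)
    mean_r, var_r, _ = _group_stats(X, ~mask)
    t, p = overestimated_var_ttest(mean_g, var_g, n_group, mean_r, var_r)
    eps = 1e-9
    lfc = np.log2((np.expm1(mean_g) + eps) / (np.expm1(mean_r) + eps))
    out = pd.DataFrame(
        {
            "gene": lognorm.feature_names,
            "mean_group": mean_g,
            "mean_rest": mean_r,
            "log2_fold_change": lfc,
            "t": t,
            "p": p,
            "p_adj": bh_adjust(p),
        }
    )
    # descending t; ties broken by gene name for a deterministic ranking
    out = out.sort_values(["t", "gene"], ascending=[False, True], kind="mergesort")
    return out.reset_index(drop=True)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment: p_(i) * m / i with a running
    minimum from the largest p downward, clipped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def go_enrichment(
    de_result: "pd.DataFrame | list[str]",
    annotations: dict[str, set[str]],
    universe: "set[str] | list[str]",
    n_top: int = 50,
    min_size: int = 6,
    max_size: int = 499,
    term_names: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Hypergeometric GO enrichment of the top-ranked genes.

    Term gene sets are intersected with the universe before the size filter
    (kept iff min_size <= K <= max_size, i.e. more than five and fewer than
    500 genes at the defaults).  For each surviving term with K annotated
    genes and overlap k with the ``n_top`` genes, p = P(X >= k) under
    X ~ Hypergeometric(N=|universe|, K, n_top); k = 0 gives p = 1 exactly.
    BH correction runs across the surviving terms only.
    """
    universe = set(universe)
    n_univ = len(universe)
    if n_top > n_univ:
        raise ValueError(f"n_top={n_top} exceeds universe size {n_univ}")
    if isinstance(de_result, pd.DataFrame):
        ranked = de_result["gene"].tolist()
    else:
        ranked = list(de_result)
    top = [g for g in ranked if g in universe][:n_top]
    top_set = set(top)

    rows = []
    for term, genes in annotations.items():
        in_univ = genes & universe
        K = len(in_univ)
        if not min_size <= K <= max_size:
            continue
        k = len(in_univ & top_set)
        p = float(stats.hypergeom.sf(k - 1, n_univ, K, len(top)))
        rows.append(
            dict(
                term=term,
                name=(term_names or {}).get(term, ""),
                term_size=K,
                overlap=k,
                p=min(p, 1.0),
            )
        )
    result = pd.DataFrame(rows, columns=["term", "name", "term_size", "overlap", "p"])
    if len(result):
        result["p_adj"] = bh_adjust(result["p"].to_numpy())
        result = result.sort_values(["p", "term"], kind="mergesort").reset_index(drop=True)
    else:
        result["p_adj"] = pd.Series(dtype=float)
    return result
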