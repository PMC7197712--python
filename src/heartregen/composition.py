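"""Cluster-composition tables and dotplot summary statistics.

Only the numbers behind the plots are computed here; rendering is out of
scope.  Two dotplot scalings are provided, matching the two figure styles:

* max-scaled: per gene, the group mean divided by its maximum over groups,
  and the expressing-cell count likewise divided by its maximum;
* min-max: per gene, (group mean - min over groups) scaled so the largest
  min-subtracted value is 1, with the dot size as the plain fraction of
  expressing cells in the group.

"Expressing" means a non-zero count, consistent with the gating semantics
(log-normalisation preserves the zero pattern).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import ExpressionMatrix


def cluster_sample_counts(labels: np.ndarray, samples: np.ndarray) -> pd.DataFrame:
    """Exhaustive cluster x sample cross-tabulation of cell counts."""
    labels = np.asarray(labels)
    samples = np.asarray(samples)
    if labels.shape[0] != samples.shape[0]:
        raise ValueError(
            f"{labels.shape[0]} labels vs {samples.shape[0]} sample entries"
        )
    if labels.size == 0:
        return pd.DataFrame()
    return pd.crosstab(
        pd.Series(labels, name="cluster"), pd.Series(samples, name="sample")
    )


def _gene_group_stats(
    lognorm: ExpressionMatrix, genes: list[str], groups: np.ndarray
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """(mean, n_expressing, group size) tables, genes x groups."""
    groups = np.asarray(groups, dtype=object).astype(str)
    if groups.shape[0] != lognorm.n_cells:
        raise ValueError("group labels misaligned with cells")
    name_to_idx = {n: i for i, n in enumerate(lognorm.feature_names)}
    missing = [g for g in genes if g not in name_to_idx]
    if missing:
        raise KeyError(f"genes not in matrix: {missing}")
    idx = [name_to_idx[g] for g in genes]
    sub = np.asarray(lognorm.X[:, idx].todense())
    uniq = list(pd.unique(groups))
    means, n_expr, sizes = {}, {}, {}
    for g in uniq:
        sel = groups == g
        n = int(sel.sum())
        if n == 0:
            raise ValueError(f"empty group {g!r}")
        means[g] = sub[sel].mean(axis=0)
        n_expr[g] = (sub[sel] > 0).sum(axis=0)
        sizes[g] = n
    mean_df = pd.DataFrame(means, index=genes)
    expr_df = pd.DataFrame(n_expr, index=genes)
    size_df = pd.DataFrame({g: [sizes[g]] * len(genes) for g in uniq}, index=genes)
    return mean_df, expr_df, size_df


def dotplot_stats_max_scaled(
    lognorm: ExpressionMatrix, genes: list[str], groups: np.ndarray
) -> pd.DataFrame:
    """Max-scaled dotplot statistics.

    Returns a long table (gene, group, scaled_mean, scaled_expressing) where
    scaled_mean = group mean / max over groups and scaled_expressing =
    expressing-cell count / max over groups; both 0 when the maximum is 0.
    """
    mean_df, expr_df, _ = _gene_group_stats(lognorm, genes, groups)
    mean_max = mean_df.max(axis=1)
    expr_max = expr_df.max(axis=1)
    scaled_mean = mean_df.div(mean_max.replace(0, np.nan), axis=0).fillna(0.0)
    scaled_expr = expr_df.div(expr_max.replace(0, np.nan), axis=0).fillna(0.0)
    out = []
    for g in mean_df.columns:
        out.append(
            pd.DataFrame(
                {
                    "gene": genes,
                    "group": g,
                    "scaled_mean": scaled_mean[g].to_numpy(),
                    "scaled_expressing": scaled_expr[g].to_numpy(),
                }
            )
        )
    return pd.concat(out, ignore_index=True)


def dotplot_stats_minmax(
    lognorm: ExpressionMatrix,
    genes: list[str],
    groups: np.ndarray,
    divide_by_range: bool = True,
) -> pd.DataFrame:
    """Min-max dotplot statistics.

    scaled_mean = (group mean - min over groups) / max of the min-subtracted
    values (equivalently the range), mapping the smallest group to 0 and the
    largest to 1; all 0 when every group mean is equal.  ``divide_by_range``
    False divides the min-subtracted values by the maximum of the *original*
    means instead (an alternative reading of the same scaling).  The dot size
    is the plain fraction of expressing cells per group.
    """
    mean_df, expr_df, size_df = _gene_group_stats(lognorm, genes, groups)
    if mean_df.shape[1] < 2:
        raise ValueError("min-max scaling needs at least 2 groups")
    mins = mean_df.min(axis=1)
    shifted = mean_df.sub(mins, axis=0)
    denom = shifted.max(axis=1) if divide_by_range else mean_df.max(axis=1)
    scaled = shifted.div(denom.replace(0, np.nan), axis=0).fillna(0.0)
    frac = expr_df / size_df
    out = []
    for g in mean_df.columns:
        out.append(
            pd.DataFrame(
                {
                    "gene": genes,
                    "group": g,
                    "scaled_mean": scaled[g].to_numpy(),
                    "expressing_fraction": frac[g].to_numpy(),
                }
            )
        )
    return pd.concat(out, ignore_index=True)
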