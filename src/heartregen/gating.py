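"""Reporter-transgene gating and population tabulation.

Cells are called positive for a reporter when they carry at least one UMI
summed over that reporter's positivity feature set, on raw (unnormalised)
counts:

* mChr+  : >=1 UMI across mCherry, mCherry-plasmid-backbone, mCherry-polyA
* Cit+   : >=1 UMI across Citrine, Citrine-polyA, Citrine-Remaining
  (the other four Citrine plasmid contents are carried in the matrix but do
  not confer positivity)
* kdrl+ / runx1+ : >=1 UMI in the endogenous gene

Composite gates: kdrl+mChr+ = kdrl+ OR mChr+; runx1+Cit+ = runx1+ OR Cit+;
double+ = kdrl+mChr+ AND runx1+Cit+.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CountMatrix

POPULATIONS = (
    "mChr+",
    "Cit+",
    "kdrl+",
    "runx1+",
    "kdrl+mChr+",
    "runx1+Cit+",
    "double+",
)


@dataclass(frozen=True)
class ReporterFeatureMap:
    """Feature names backing each gate.  The positivity sets are pairwise
    disjoint; the four extra Citrine plasmid contents never confer
    positivity."""

    mcherry_features: tuple[str, ...] = (
        "mCherry",
        "mCherry-plasmid-backbone",
        "mCherry-polyA",
    )
    citrine_positive_features: tuple[str, ...] = (
        "Citrine",
        "Citrine-polyA",
        "Citrine-Remaining",
    )
    citrine_other_features: tuple[str, ...] = (
        "Citrine-3x-HA-tag",
        "Citrine-BirA",
        "Citrine-Tav-2a",
        "Citrine-Frt1",
    )
    kdrl_gene: str = "kdrl"
    runx1_gene: str = "runx1"

    def __post_init__(self) -> None:
        sets = [
            set(self.mcherry_features),
            set(self.citrine_positive_features),
            set(self.citrine_other_features),
            {self.kdrl_gene},
            {self.runx1_gene},
        ]
        if not self.mcherry_features or not self.citrine_positive_features:
            raise ValueError("positivity feature sets must be non-empty")
        union = set().union(*sets)
        if len(union) != sum(len(s) for s in sets):
            raise ValueError("reporter feature sets must be pairwise disjoint")


def _feature_sum(matrix: CountMatrix, names: tuple[str, ...]) -> np.ndarray:
    idx = [matrix.feature_index(n) for n in names]
    return np.asarray(matrix.X[:, idx].sum(axis=1)).ravel()


def classify_cells(
    matrix: CountMatrix,
    fmap: ReporterFeatureMap | None = None,
    min_umi: int = 1,
) -> pd.DataFrame:
    """Per-cell Boolean gate calls on raw counts.

    Returns a DataFrame indexed by barcode with columns mChr, Cit, kdrl,
    runx1, kdrl_mChr, runx1_Cit, double.  Raises KeyError if any mapped
    feature is absent from the matrix.  ``min_umi`` defaults to the published
    >=1-UMI rule; it is exposed only for sensitivity analysis.
    """
    fmap = fmap or ReporterFeatureMap()
    mchr = _feature_sum(matrix, fmap.mcherry_features) >= min_umi
    cit = _feature_sum(matrix, fmap.citrine_positive_features) >= min_umi
    kdrl = _feature_sum(matrix, (fmap.kdrl_gene,)) >= min_umi
    runx1 = _feature_sum(matrix, (fmap.runx1_gene,)) >= min_umi
    kdrl_mchr = kdrl | mchr
    runx1_cit = runx1 | cit
    flags = pd.DataFrame(
        {
            "mChr": mchr,
            "Cit": cit,
            "kdrl": kdrl,
            "runx1": runx1,
            "kdrl_mChr": kdrl_mchr,
            "runx1_Cit": runx1_cit,
            "double": kdrl_mchr & runx1_cit,
        },
        index=pd.Index(matrix.barcodes, name="barcode"),
    )
    return flags


_FLAG_FOR_POPULATION = {
    "mChr+": "mChr",
    "Cit+": "Cit",
    "kdrl+": "kdrl",
    "runx1+": "runx1",
    "kdrl+mChr+": "kdrl_mChr",
    "runx1+Cit+": "runx1_Cit",
    "double+": "double",
}


def tabulate_populations(flags: pd.DataFrame, samples: np.ndarray) -> pd.DataFrame:
    """Population counts and percentages per sample (the marker-based cell
    count table).

    One row per population; for each sample a ``count`` and a ``pct`` column,
    where pct = 100 * count / retained cells in that sample.
    """
    samples = np.asarray(samples, dtype=object).astype(str)
    if len(samples) != len(flags):
        raise ValueError("sample labels misaligned with flags")
    out: dict[tuple[str, str], list[float]] = {}
    for sample in pd.unique(samples):
        sel = flags.loc[samples == sample]
        n = len(sel)
        if n == 0:
            raise ValueError(f"sample {sample!r} has no cells")
        counts = [int(sel[_FLAG_FOR_POPULATION[p]].sum()) for p in POPULATIONS]
        out[(sample, "count")] = counts
        out[(sample, "pct")] = [100.0 * c / n for c in counts]
    table = pd.DataFrame(out, index=pd.Index(POPULATIONS, name="population"))
    table.columns = pd.MultiIndex.from_tuples(table.columns, names=["sample", "stat"])
    return table
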