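"""Readers and writers for the formats the pipeline touches.

Count matrices travel as 10x-style MatrixMarket triplets (``matrix.mtx`` with
features on rows and barcodes on columns, plus ``features.tsv`` and
``barcodes.tsv``); in memory they are held cells-by-features in a
:class:`CountMatrix`.  Every writer/reader pair round-trips exactly and never
mutates values.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

#: Exact feature names of the two reporter plasmids' sequence contents, as
#: they appear in the aligned reference: three mCherry contents and seven
#: Citrine contents.
TRANSGENE_FEATURES: tuple[str, ...] = (
    "mCherry",
    "mCherry-plasmid-backbone",
    "mCherry-polyA",
    "Citrine-3x-HA-tag",
    "Citrine-BirA",
    "Citrine-Tav-2a",
    "Citrine",
    "Citrine-polyA",
    "Citrine-Frt1",
    "Citrine-Remaining",
)

FEATURE_CLASSES = ("gene", "mito", "transgene")

DEFAULT_SAMPLE = "sample1"
DEFAULT_MITO_PREFIX = "mt-"


def classify_feature_names(
    names: "pd.Series | np.ndarray | list[str]",
    mito_prefix: str = DEFAULT_MITO_PREFIX,
) -> np.ndarray:
    """Assign each feature name a class: transgene (exact-name match against
    the reporter plasmid contents), mito (name prefix, default ``mt-``) or
    gene."""
    names = pd.Series(np.asarray(names, dtype=object))
    cls = np.full(len(names), "gene", dtype=object)
    cls[names.str.startswith(mito_prefix).to_numpy()] = "mito"
    cls[names.isin(TRANSGENE_FEATURES).to_numpy()] = "transgene"
    return cls.astype(str)


@dataclass
class CountMatrix:
    """Sparse cells-by-features UMI count table.

    Attributes
    ----------
    X : scipy.sparse.csr_matrix
        Non-negative integer counts, one row per cell.
    barcodes : np.ndarray of str
        Cell barcodes; unique within each sample.
    features : pd.DataFrame
        One row per feature with columns ``name`` (unique) and
        ``feature_class`` in {gene, mito, transgene}.
    samples : np.ndarray of str
        Per-cell sample label.
    """

    X: sp.csr_matrix
    barcodes: np.ndarray
    features: pd.DataFrame
    samples: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.X = sp.csr_matrix(self.X)
        self.barcodes = np.asarray(self.barcodes, dtype=object).astype(str)
        if self.samples is None:
            self.samples = np.full(self.X.shape[0], DEFAULT_SAMPLE, dtype=object)
        self.samples = np.asarray(self.samples, dtype=object).astype(str)
        self.features = self.features.reset_index(drop=True)
        self._validate()

    def _validate(self) -> None:
        n_cells, n_feat = self.X.shape
        if len(self.barcodes) != n_cells:
            raise ValueError(
                f"{len(self.barcodes)} barcodes for {n_cells} matrix rows"
            )
        if len(self.samples) != n_cells:
            raise ValueError("sample labels misaligned with barcodes")
        if len(self.features) != n_feat:
            raise ValueError(
                f"{len(self.features)} feature rows for {n_feat} matrix columns"
            )
        if not {"name", "feature_class"} <= set(self.features.columns):
            raise ValueError("features table needs 'name' and 'feature_class'")
        if self.features["name"].duplicated().any():
            dups = self.features["name"][self.features["name"].duplicated()]
            raise ValueError(f"duplicate feature names: {sorted(set(dups))}")
        bad = set(self.features["feature_class"]) - set(FEATURE_CLASSES)
        if bad:
            raise ValueError(f"unknown feature classes: {sorted(bad)}")
        pairs = pd.DataFrame({"s": self.samples, "b": self.barcodes})
        if pairs.duplicated().any():
            raise ValueError("duplicate barcodes within a sample")
        if self.X.nnz and self.X.data.min() < 0:
            raise ValueError("negative counts")

    # -- convenience ------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def feature_names(self) -> np.ndarray:
        return self.features["name"].to_numpy()

    def feature_index(self, name: str) -> int:
        idx = np.flatnonzero(self.feature_names == name)
        if idx.size == 0:
            raise KeyError(f"feature {name!r} not in matrix")
        return int(idx[0])

    def class_mask(self, feature_class: str) -> np.ndarray:
        return (self.features["feature_class"] == feature_class).to_numpy()

    def subset_cells(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return CountMatrix(
            X=self.X[idx],
            barcodes=self.barcodes[idx],
            features=self.features.copy(),
            samples=self.samples[idx],
        )

    def subset_features(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return CountMatrix(
            X=self.X[:, idx].tocsr(),
            barcodes=self.barcodes.copy(),
            features=self.features.iloc[idx].reset_index(drop=True),
            samples=self.samples.copy(),
        )


@dataclass
class ExpressionMatrix:
    """Real-valued cells-by-features matrix (e.g. log-normalised counts)."""

    X: sp.csr_matrix
    barcodes: np.ndarray
    features: pd.DataFrame
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.X = sp.csr_matrix(self.X)
        self.features = self.features.reset_index(drop=True)

    @property
    def n_cells(self) -> int:
        return self.X.shape[0]

    @property
    def feature_names(self) -> np.ndarray:
        return self.features["name"].to_numpy()


# ---------------------------------------------------------------------------
# MTX triplet I/O
# ---------------------------------------------------------------------------

def write_counts_mtx(matrix: CountMatrix, path: str | Path, overwrite: bool = False) -> None:
    """Write a 10x-style triplet: ``matrix.mtx`` (features x cells, integer
    coordinate format), ``features.tsv`` (name, class), ``barcodes.tsv``
    (barcode, sample).  Refuses to clobber an existing triplet unless
    ``overwrite`` is set."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    targets = [path / "matrix.mtx", path / "features.tsv", path / "barcodes.tsv"]
    if not overwrite:
        existing = [t.name for t in targets if t.exists()]
        if existing:
            raise FileExistsError(
                f"refusing to overwrite {existing} in {path}; pass overwrite=True"
            )
    coo = matrix.X.T.tocoo()  # features x cells, 10x orientation
    scipy.io.mmwrite(
        str(targets[0]), coo, field="integer", comment="heartregen counts"
    )
    matrix.features[["name", "feature_class"]].to_csv(
        targets[1], sep="\t", header=False, index=False
    )
    pd.DataFrame({"barcode": matrix.barcodes, "sample": matrix.samples}).to_csv(
        targets[2], sep="\t", header=False, index=False
    )


def read_counts_mtx(path: str | Path, mito_prefix: str = DEFAULT_MITO_PREFIX) -> CountMatrix:
    """Read a triplet directory written by :func:`write_counts_mtx` or a plain
    10x v2 directory (two- or three-column features file, bare barcodes)."""
    path = Path(path)
    mtx_file = path / "matrix.mtx"
    if not mtx_file.exists():
        raise FileNotFoundError(mtx_file)
    mat = scipy.io.mmread(str(mtx_file))
    if mat.size and not np.issubdtype(mat.dtype, np.integer):
        data = mat.tocoo().data
        if not np.allclose(data, np.round(data)):
            raise ValueError(f"{mtx_file}: non-integer count entries")
    X = sp.csr_matrix(mat.T.astype(np.int64))

    feat = pd.read_csv(path / "features.tsv", sep="\t", header=None, dtype=str)
    if feat.shape[1] == 1:
        names = feat[0]
        classes = None
    elif feat.shape[1] == 2:
        names, second = feat[0], feat[1]
        # our dialect stores (name, class); 10x v2 stores (id, name)
        classes = second if second.isin(FEATURE_CLASSES).all() else None
        if classes is None:
            names = second
    else:  # 10x v3: id, name, type -- the 10x "type" is not our class
        names = feat[1]
        classes = None
    features = pd.DataFrame({"name": names.to_numpy(dtype=object)})
    if classes is not None:
        features["feature_class"] = classes.to_numpy(dtype=object)
    else:
        features["feature_class"] = classify_feature_names(
            features["name"], mito_prefix=mito_prefix
        )

    bc = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None, dtype=str)
    barcodes = bc[0].to_numpy(dtype=object)
    samples = (
        bc[1].to_numpy(dtype=object)
        if bc.shape[1] >= 2
        else np.full(len(barcodes), DEFAULT_SAMPLE, dtype=object)
    )

    if X.shape[0] != len(barcodes) or X.shape[1] != len(features):
        raise ValueError(
            f"dimension mismatch: matrix {X.shape[0]}x{X.shape[1]} vs "
            f"{len(barcodes)} barcodes / {len(features)} features"
        )
    return CountMatrix(X=X, barcodes=barcodes, features=features, samples=samples)


# ---------------------------------------------------------------------------
# GO annotation table
# ---------------------------------------------------------------------------

def read_go_table(path: str | Path) -> tuple[dict[str, set[str]], dict[str, str]]:
    """Read a ZFIN-style gene-to-term annotation table.

    Expects tab-delimited rows ``gene<TAB>term_id[<TAB>term_name]``; lines
    starting with ``#`` are skipped.  Duplicate gene-term pairs collapse to a
    single membership.  Returns ``(term -> gene set, term -> name)``.
    Malformed rows raise with their line number.
    """
    terms: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0] or not fields[1]:
                raise ValueError(
                    f"{path}:{lineno}: expected 'gene<TAB>term[<TAB>name]', got {line!r}"
                )
            gene, term = fields[0], fields[1]
            terms.setdefault(term, set()).add(gene)
            if len(fields) >= 3 and fields[2]:
                names[term] = fields[2]
    return terms, names


def write_go_table(
    terms: dict[str, set[str]],
    path: str | Path,
    names: dict[str, str] | None = None,
) -> None:
    names = names or {}
    with open(path, "w") as fh:
        for term in sorted(terms):
            for gene in sorted(terms[term]):
                name = names.get(term, "")
                row = [gene, term] + ([name] if name else [])
                fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# Images
# ---------------------------------------------------------------------------

def read_image(path: str | Path) -> np.ndarray:
    """Read an 8- or 16-bit RGB raster to a float array in [0, 1], channel
    order R, G, B.  Non-RGB input (grayscale, palette) is rejected; an alpha
    channel is dropped."""
    arr = iio.imread(path)
    if arr.ndim != 3 or arr.shape[2] not in (3, 4):
        raise ValueError(f"{path}: expected RGB image, got shape {arr.shape}")
    arr = arr[:, :, :3]
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0
    raise ValueError(f"{path}: unsupported dtype {arr.dtype}")


def write_image(image: np.ndarray, path: str | Path) -> None:
    """Write a float RGB image in [0, 1] as an 8-bit PNG."""
    arr = np.clip(np.asarray(image, dtype=np.float64), 0.0, 1.0)
    iio.imwrite(Path(path), np.round(arr * 255.0).astype(np.uint8))


def read_mask(path: str | Path) -> np.ndarray:
    """Read a single-channel (or RGB, any-channel-nonzero) mask as boolean."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[:, :, :3].max(axis=2)
    return arr > 0


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    iio.imwrite(Path(path), (np.asarray(mask, dtype=bool) * np.uint8(255)))
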