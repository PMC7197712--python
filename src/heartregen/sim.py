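"""Synthetic data with planted ground truth.

Generates everything the pipeline consumes: UMI count matrices with reporter
transgene features, doublets and low-complexity cells; AFOG-like trichrome
wound images; nuclei tables for proliferation indexing; and GO annotation
universes.  The planted labels emitted alongside each artefact are the oracle
against which every downstream stage is checked.

The expression model is a per-cell-type negative binomial: gene g in a cell of
type t draws NB with mean mu_{t,g} and a common per-type dispersion d (variance
mu + d*mu^2).  Transgene features are Poisson conditioned on the cell's true
reporter status.  Doublets are exact elementwise sums of two sampled singlet
profiles; low-quality cells are constructed to express fewer than 100 features
while every other singlet is topped up to at least 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import (
    TRANSGENE_FEATURES,
    CountMatrix,
    classify_feature_names,
)

MCHERRY_FEATURES = TRANSGENE_FEATURES[:3]
CITRINE_FEATURES = TRANSGENE_FEATURES[3:]

#: Expressed-feature threshold separating planted low-quality cells (strictly
#: below) from ordinary singlets (at or above); mirrors the QC min-genes rule.
LOWQ_FEATURE_LIMIT = 100

# AFOG palette on [0,1] RGB: fibrin stains bright red, collagen blue,
# muscle/other orange.  Channel values sit well away from the default 0.6
# red/blue thresholds so moderate Gaussian noise does not flip classes.
AFOG_COLORS = {
    "fibrin": (0.95, 0.15, 0.15),
    "collagen": (0.20, 0.30, 0.85),
    "other": (0.45, 0.30, 0.10),
}
AFOG_BACKGROUND = (0.92, 0.90, 0.88)


# ---------------------------------------------------------------------------
# Config types
# ---------------------------------------------------------------------------

@dataclass
class CellTypeSpec:
    """One simulated cell population.

    ``mean`` is the per-gene NB mean vector (length n_genes); ``dispersion``
    the NB dispersion d in var = mu + d*mu^2.  ``mcherry``/``citrine`` give the
    population's true reporter status; kdrl/runx1 truth follows from whether
    the mean vector is positive at those marker genes.
    """

    name: str
    n_cells: int
    mean: np.ndarray
    dispersion: float = 0.3
    mcherry: bool = False
    citrine: bool = False


@dataclass
class SimCountConfig:
    n_genes: int
    cell_types: list[CellTypeSpec]
    transgene_emission: dict[str, dict[str, float]] = field(default_factory=dict)
    doublet_fraction: float = 0.0
    lowq_fraction: float = 0.0
    mito_gene_fraction: float = 0.05
    mito_prefix: str = "mt-"
    samples: dict[str, dict[str, float]] = field(
        default_factory=lambda: {"sample1": {}}
    )
    seed: int = 0
    kdrl_gene: str = "kdrl"
    runx1_gene: str = "runx1"
    #: When set, reporter-positive cells are guaranteed >=1 UMI in the
    #: canonical transgene feature and in their marker gene, making gating
    #: truth exactly recoverable (noiseless emission).
    guaranteed_reporter_umi: bool = False

    def validate(self) -> None:
        if self.n_genes < LOWQ_FEATURE_LIMIT:
            raise ValueError(
                f"n_genes must be >= {LOWQ_FEATURE_LIMIT} to separate "
                "low-quality cells from singlets"
            )
        for frac, label in [
            (self.doublet_fraction, "doublet_fraction"),
            (self.lowq_fraction, "lowq_fraction"),
        ]:
            if not 0.0 <= frac < 1.0:
                raise ValueError(f"{label} must be in [0, 1), got {frac}")
        if not 0.0 <= self.mito_gene_fraction < 1.0:
            raise ValueError("mito_gene_fraction must be in [0, 1)")
        if self.doublet_fraction + self.lowq_fraction >= 1.0:
            raise ValueError("doublet_fraction + lowq_fraction must be < 1")
        if not self.cell_types:
            raise ValueError("at least one cell type required")
        for ct in self.cell_types:
            if len(ct.mean) != self.n_genes:
                raise ValueError(
                    f"cell type {ct.name!r}: mean vector length "
                    f"{len(ct.mean)} != n_genes {self.n_genes}"
                )
            if np.any(np.asarray(ct.mean) < 0):
                raise ValueError(f"cell type {ct.name!r}: negative NB means")
            if ct.dispersion < 0:
                raise ValueError(f"cell type {ct.name!r}: negative dispersion")
        for status, rates in self.transgene_emission.items():
            for feat, rate in rates.items():
                if rate < 0:
                    raise ValueError(
                        f"negative Poisson rate for {feat!r} under {status!r}"
                    )
        if not self.samples:
            raise ValueError("at least one sample required")

    def gene_names(self) -> list[str]:
        """Gene namespace: kdrl and runx1 first, a mito block (name prefix)
        last, numbered filler genes between."""
        n_mito = int(round(self.mito_gene_fraction * self.n_genes))
        names = [self.kdrl_gene, self.runx1_gene]
        n_fill = self.n_genes - 2 - n_mito
        names += [f"gene{i:05d}" for i in range(n_fill)]
        names += [f"{self.mito_prefix}gene{i:03d}" for i in range(n_mito)]
        return names


GROUND_TRUTH_COLUMNS = [
    "barcode",
    "sample",
    "cell_type",
    "is_doublet",
    "is_lowq",
    "mcherry",
    "citrine",
    "kdrl",
    "runx1",
    "parent_barcodes",
]


# ---------------------------------------------------------------------------
# Count simulation
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float, n: int) -> np.ndarray:
    """Draw n cells from NB(mean, dispersion); dispersion 0 degenerates to
    Poisson."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros((n, mean.size), dtype=np.int64)
    pos = mean > 0
    if not pos.any():
        return out
    if dispersion <= 0:
        out[:, pos] = rng.poisson(mean[pos], size=(n, pos.sum()))
        return out
    r = 1.0 / dispersion
    p = r / (r + mean[pos])
    out[:, pos] = rng.negative_binomial(r, p, size=(n, pos.sum()))
    return out


def _transgene_rates(config: SimCountConfig, mcherry: bool, citrine: bool) -> np.ndarray:
    rates = np.zeros(len(TRANSGENE_FEATURES))
    key_m = "mcherry_pos" if mcherry else "mcherry_neg"
    key_c = "citrine_pos" if citrine else "citrine_neg"
    for key in (key_m, key_c):
        for feat, rate in config.transgene_emission.get(key, {}).items():
            rates[TRANSGENE_FEATURES.index(feat)] = rate
    return rates


def _topup_singlets(rng: np.random.Generator, counts: np.ndarray) -> None:
    """Ensure every row expresses at least LOWQ_FEATURE_LIMIT features by
    placing single UMIs on randomly chosen silent genes (in place)."""
    expressed = (counts > 0).sum(axis=1)
    for i in np.flatnonzero(expressed < LOWQ_FEATURE_LIMIT):
        silent = np.flatnonzero(counts[i] == 0)
        need = LOWQ_FEATURE_LIMIT - int(expressed[i])
        pick = rng.choice(silent, size=need, replace=False)
        counts[i, pick] = 1


def simulate_sample(
    config: SimCountConfig, sample: str
) -> tuple[CountMatrix, pd.DataFrame]:
    """Simulate one sample's count matrix plus its ground-truth table.

    The emitted barcode set is singlets (the per-type cell numbers after the
    sample's composition multipliers) plus ``doublet_fraction`` doublets and
    ``lowq_fraction`` low-quality cells of the total.  Deterministic for a
    fixed (config.seed, sample) pair.
    """
    config.validate()
    if sample not in config.samples:
        raise KeyError(f"sample {sample!r} not declared in config")
    sample_idx = list(config.samples).index(sample)
    rng = np.random.default_rng([config.seed, sample_idx])
    overrides = config.samples[sample]
    unknown = set(overrides) - {ct.name for ct in config.cell_types}
    if unknown:
        raise ValueError(f"composition override for unknown cell types {unknown}")

    gene_names = config.gene_names()
    kdrl_idx = gene_names.index(config.kdrl_gene)
    runx1_idx = gene_names.index(config.runx1_gene)

    blocks: list[np.ndarray] = []
    tg_blocks: list[np.ndarray] = []
    meta: list[dict] = []
    for ct in config.cell_types:
        n = int(round(ct.n_cells * overrides.get(ct.name, 1.0)))
        if n < 0:
            raise ValueError(f"negative cell count for {ct.name!r}")
        if n == 0:
            continue
        counts = _nb_draw(rng, ct.mean, ct.dispersion, n)
        kdrl_pos = ct.mean[kdrl_idx] > 0
        runx1_pos = ct.mean[runx1_idx] > 0
        if config.guaranteed_reporter_umi:
            if kdrl_pos:
                counts[:, kdrl_idx] = np.maximum(counts[:, kdrl_idx], 1)
            if runx1_pos:
                counts[:, runx1_idx] = np.maximum(counts[:, runx1_idx], 1)
        _topup_singlets(rng, counts)
        rates = _transgene_rates(config, ct.mcherry, ct.citrine)
        tg = rng.poisson(rates, size=(n, len(TRANSGENE_FEATURES)))
        tg[:, rates == 0] = 0
        if config.guaranteed_reporter_umi:
            if ct.mcherry:
                j = TRANSGENE_FEATURES.index("mCherry")
                tg[:, j] = np.maximum(tg[:, j], 1)
            if ct.citrine:
                j = TRANSGENE_FEATURES.index("Citrine")
                tg[:, j] = np.maximum(tg[:, j], 1)
        blocks.append(counts)
        tg_blocks.append(tg)
        meta.extend(
            [
                dict(
                    cell_type=ct.name,
                    mcherry=ct.mcherry,
                    citrine=ct.citrine,
                    kdrl=bool(kdrl_pos),
                    runx1=bool(runx1_pos),
                )
            ]
            * n
        )
    if not meta:
        raise ValueError(f"sample {sample!r} requests zero cells")

    sing = np.vstack(blocks)
    sing_tg = np.vstack(tg_blocks)
    n_sing = sing.shape[0]

    # emitted total T solves n_sing = T * (1 - f_d - f_lq)
    frac_rest = 1.0 - config.doublet_fraction - config.lowq_fraction
    total = int(round(n_sing / frac_rest))
    n_doub = int(round(config.doublet_fraction * total))
    n_lowq = total - n_sing - n_doub

    rows = [np.hstack([sing, sing_tg])]
    truth_rows = [
        dict(
            sample=sample,
            cell_type=m["cell_type"],
            is_doublet=False,
            is_lowq=False,
            mcherry=m["mcherry"],
            citrine=m["citrine"],
            kdrl=m["kdrl"],
            runx1=m["runx1"],
            parent_barcodes="",
        )
        for m in meta
    ]
    singlet_ids = np.arange(n_sing)

    if n_doub > 0:
        pairs = np.array(
            [rng.choice(n_sing, size=2, replace=False) for _ in range(n_doub)]
        )
        doub = (
            np.hstack([sing, sing_tg])[pairs[:, 0]]
            + np.hstack([sing, sing_tg])[pairs[:, 1]]
        )
        rows.append(doub)
        for a, b in pairs:
            ma, mb = meta[a], meta[b]
            truth_rows.append(
                dict(
                    sample=sample,
                    cell_type=f"{ma['cell_type']}+{mb['cell_type']}",
                    is_doublet=True,
                    is_lowq=False,
                    mcherry=ma["mcherry"] or mb["mcherry"],
                    citrine=ma["citrine"] or mb["citrine"],
                    kdrl=ma["kdrl"] or mb["kdrl"],
                    runx1=ma["runx1"] or mb["runx1"],
                    parent_barcodes=f"{int(a)};{int(b)}",  # filled below
                )
            )

    if n_lowq > 0:
        lowq = np.zeros((n_lowq, config.n_genes + len(TRANSGENE_FEATURES)), dtype=np.int64)
        for i in range(n_lowq):
            k = int(rng.integers(10, LOWQ_FEATURE_LIMIT))
            genes = rng.choice(config.n_genes, size=k, replace=False)
            lowq[i, genes] = rng.integers(1, 4, size=k)
        rows.append(lowq)
        truth_rows.extend(
            [
                dict(
                    sample=sample,
                    cell_type="low_quality",
                    is_doublet=False,
                    is_lowq=True,
                    mcherry=False,
                    citrine=False,
                    kdrl=False,
                    runx1=False,
                    parent_barcodes="",
                )
            ]
            * n_lowq
        )

    full = np.vstack(rows)
    order = rng.permutation(full.shape[0])
    full = full[order]
    truth = pd.DataFrame([truth_rows[i] for i in order])

    barcodes = np.array(
        [f"{sample}-BC{i:06d}" for i in range(full.shape[0])], dtype=object
    )
    # parent references were singlet draw ids; remap to emitted barcodes
    pos_of_singlet = {}
    for new_pos, old_pos in enumerate(order):
        if old_pos < n_sing:
            pos_of_singlet[old_pos] = new_pos
    remapped = []
    for p in truth["parent_barcodes"]:
        if p:
            a, b = (int(x) for x in p.split(";"))
            remapped.append(
                f"{barcodes[pos_of_singlet[a]]};{barcodes[pos_of_singlet[b]]}"
            )
        else:
            remapped.append("")
    truth["parent_barcodes"] = remapped
    truth.insert(0, "barcode", barcodes)

    feature_names = gene_names + list(TRANSGENE_FEATURES)
    features = pd.DataFrame(
        {
            "name": feature_names,
            "feature_class": classify_feature_names(
                feature_names, mito_prefix=config.mito_prefix
            ),
        }
    )
    matrix = CountMatrix(
        X=sp.csr_matrix(full),
        barcodes=barcodes,
        features=features,
        samples=np.full(full.shape[0], sample, dtype=object),
    )
    return matrix, truth[GROUND_TRUTH_COLUMNS]


def simulate_dataset(config: SimCountConfig) -> tuple[CountMatrix, pd.DataFrame]:
    """Simulate and concatenate every sample declared in the config."""
    mats, truths = [], []
    for sample in config.samples:
        m, t = simulate_sample(config, sample)
        mats.append(m)
        truths.append(t)
    X = sp.vstack([m.X for m in mats]).tocsr()
    matrix = CountMatrix(
        X=X,
        barcodes=np.concatenate([m.barcodes for m in mats]),
        features=mats[0].features,
        samples=np.concatenate([m.samples for m in mats]),
    )
    return matrix, pd.concat(truths, ignore_index=True)


# ---------------------------------------------------------------------------
# Default study-like configuration
# ---------------------------------------------------------------------------

def _type_mean(
    rng: np.random.Generator,
    base: np.ndarray,
    marker_slice: slice,
    library_size: float,
    marker_boost: float = 20.0,
) -> np.ndarray:
    # markers get a flat elevated mean: strongly type-discriminative without
    # pushing genes past the abundance window of HVG selection
    mean = base.copy()
    mean[marker_slice] = marker_boost * base.mean()
    return mean * (library_size / mean.sum())


def default_config(
    n_genes: int = 2000,
    scale: float = 1.0,
    library_size: float = 2500.0,
    seed: int = 0,
) -> SimCountConfig:
    """Study-like three-sample design: uninjured wild type, injured wild type,
    injured runx1 mutant.

    Populations carry the composition structure the analysis is sensitive to:
    injury-specific endocardial cells appear only in injured samples, and the
    thrombocyte and myofibroblast populations are absent or depleted in the
    mutant.  Per-sample totals land near post-QC scale (thousands of cells) at
    ``scale=1``; pass a smaller ``scale`` for quick fixtures.
    """
    rng = np.random.default_rng(seed)
    base = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    base[:2] = 0.0  # kdrl, runx1 are assigned per type below
    n_mito = int(round(0.05 * n_genes))
    block = max(1, (n_genes - 2 - n_mito) // 14)

    def mk(name, n, block_idx, mcherry=False, citrine=False, kdrl=0.0, runx1=0.0):
        start = 2 + block_idx * block
        mean = _type_mean(rng, base, slice(start, start + block), library_size)
        mean[0] = kdrl
        mean[1] = runx1
        return CellTypeSpec(
            name=name,
            n_cells=max(2, int(round(n * scale))),
            mean=mean,
            dispersion=0.3,
            mcherry=mcherry,
            citrine=citrine,
        )

    cell_types = [
        mk("cardiomyocyte", 100, 0),
        mk("endocardium", 1500, 1, mcherry=True, kdrl=3.0),
        mk("endocardium_injury", 700, 2, mcherry=True, citrine=True, kdrl=3.0, runx1=1.5),
        mk("thrombocyte", 600, 3, citrine=True, runx1=2.0),
        mk("myofibroblast", 300, 4, citrine=True, runx1=1.5),
        mk("immune", 1200, 5),
        mk("epicardium", 500, 6),
    ]
    emission = {
        "mcherry_pos": {
            "mCherry": 1.5,
            "mCherry-plasmid-backbone": 0.3,
            "mCherry-polyA": 0.8,
        },
        "mcherry_neg": {},
        "citrine_pos": {
            "Citrine": 1.5,
            "Citrine-polyA": 0.8,
            "Citrine-Remaining": 0.4,
            "Citrine-3x-HA-tag": 0.3,
            "Citrine-BirA": 0.2,
            "Citrine-Tav-2a": 0.2,
            "Citrine-Frt1": 0.2,
        },
        "citrine_neg": {},
    }
    samples = {
        "wt_uninjured": {"endocardium_injury": 0.0, "myofibroblast": 0.0},
        "wt_3dpci": {},
        "runx1_3dpci": {"thrombocyte": 0.0, "myofibroblast": 0.15,
                        "endocardium_injury": 1.2},
    }
    return SimCountConfig(
        n_genes=n_genes,
        cell_types=cell_types,
        transgene_emission=emission,
        doublet_fraction=0.08,
        lowq_fraction=0.02,
        mito_gene_fraction=0.05,
        samples=samples,
        seed=seed,
    )


def planted_types_config(
    n_types: int = 4,
    cells_per_type: int = 300,
    n_genes: int = 1000,
    library_size: float = 2500.0,
    marker_boost: float = 40.0,
    dispersion: float = 0.2,
    doublet_fraction: float = 0.0,
    lowq_fraction: float = 0.0,
    seed: int = 0,
) -> SimCountConfig:
    """Single-sample design with ``n_types`` well-separated populations, each
    marked by its own flat block of elevated genes; the fixture for
    clustering parameter-recovery checks.  The default boost/dispersion make
    the planted types clear a 0.5 silhouette in the pipeline's PCA space."""
    rng = np.random.default_rng(seed)
    base = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    base[:2] = 0.0
    block = (n_genes - 2) // (n_types + 2)
    cell_types = []
    for i in range(n_types):
        start = 2 + i * block
        mean = _type_mean(
            rng, base, slice(start, start + block), library_size, marker_boost
        )
        cell_types.append(
            CellTypeSpec(
                name=f"type{i + 1}",
                n_cells=cells_per_type,
                mean=mean,
                dispersion=dispersion,
            )
        )
    return SimCountConfig(
        n_genes=n_genes,
        cell_types=cell_types,
        doublet_fraction=doublet_fraction,
        lowq_fraction=lowq_fraction,
        mito_gene_fraction=0.05,
        samples={"sample1": {}},
        seed=seed,
    )


# ---------------------------------------------------------------------------
# AFOG-like wound images
# ---------------------------------------------------------------------------

@dataclass
class SimulatedAFOG:
    image: np.ndarray  # H x W x 3 float in [0,1]
    mask: np.ndarray  # H x W bool, wound region
    labels: np.ndarray  # H x W int: 0 fibrin, 1 collagen, 2 other, -1 outside
    fractions: dict[str, float]  # exact planted area fractions


def simulate_afog_image(
    fractions: dict[str, float],
    size: tuple[int, int] = (200, 200),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> SimulatedAFOG:
    """Paint a trichrome-like wound: a disk-shaped wound mask whose pixels are
    fibrin-red, collagen-blue or other-orange in the requested area fractions
    (largest-remainder apportionment, exact to +/-1 pixel), plus Gaussian
    pixel noise.  Bit-identical for a fixed seed."""
    keys = ("fibrin", "collagen", "other")
    fr = np.array([float(fractions.get(k, 0.0)) for k in keys])
    if np.any(fr < 0):
        raise ValueError("fractions must be non-negative")
    if abs(fr.sum() - 1.0) > 1e-6:
        raise ValueError(f"fractions must sum to 1, got {fr.sum()}")

    rng = np.random.default_rng(seed)
    h, w = size
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    radius = 0.38 * min(h, w)
    mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
    area = int(mask.sum())

    # largest-remainder apportionment of mask pixels to the three classes
    raw = fr * area
    counts = np.floor(raw).astype(int)
    rem = area - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:rem]] += 1

    labels = np.full((h, w), -1, dtype=int)
    pix = np.flatnonzero(mask.ravel())
    pix = rng.permutation(pix)
    flat = labels.ravel()
    start = 0
    for cls, c in enumerate(counts):
        flat[pix[start : start + c]] = cls
        start += c
    labels = flat.reshape(h, w)

    image = np.empty((h, w, 3), dtype=np.float64)
    image[:] = AFOG_BACKGROUND
    for cls, key in enumerate(keys):
        image[labels == cls] = AFOG_COLORS[key]
    if noise_sd > 0:
        image = image + rng.normal(0.0, noise_sd, size=image.shape)
    image = np.clip(image, 0.0, 1.0)

    truth = {k: counts[i] / area for i, k in enumerate(keys)}
    return SimulatedAFOG(image=image, mask=mask, labels=labels, fractions=truth)


# ---------------------------------------------------------------------------
# Nuclei tables
# ---------------------------------------------------------------------------

def simulate_nuclei_table(
    n_sections: int,
    mef2_per_section: int,
    pcna_fraction: float,
    seed: int = 0,
    fish_id: str = "fish1",
    remote_pcna_fraction: float | None = None,
    nonmyocyte_per_section: int = 30,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Nuclei table with per-nucleus Mef2/PCNA flags and border/remote zone.

    Border-zone Mef2+ nuclei are PCNA+ with probability ``pcna_fraction``
    (remote zone: ``remote_pcna_fraction``, defaulting to the same); Mef2-
    nuclei model non-myocytes and are never PCNA-flagged here.  Returns the
    table plus a truth dict with the planted and realised border-zone
    double-positive fractions.
    """
    if n_sections < 1:
        raise ValueError("n_sections must be >= 1")
    if mef2_per_section < 0 or nonmyocyte_per_section < 0:
        raise ValueError("negative nucleus counts")
    if not 0.0 <= pcna_fraction <= 1.0:
        raise ValueError("pcna_fraction must be in [0, 1]")
    remote_frac = pcna_fraction if remote_pcna_fraction is None else remote_pcna_fraction

    rng = np.random.default_rng(seed)
    rows = []
    for s in range(1, n_sections + 1):
        for zone, frac in (("border", pcna_fraction), ("remote", remote_frac)):
            pcna = rng.random(mef2_per_section) < frac
            for flag in pcna:
                rows.append((fish_id, f"sec{s}", zone, True, bool(flag)))
            for _ in range(nonmyocyte_per_section):
                rows.append((fish_id, f"sec{s}", zone, False, False))
    table = pd.DataFrame(
        rows, columns=["fish", "section", "zone", "mef2", "pcna"]
    )
    border = table[(table["zone"] == "border") & table["mef2"]]
    realised = float(border["pcna"].mean()) if len(border) else float("nan")
    truth = {"planted_fraction": float(pcna_fraction), "realised_fraction": realised}
    return table, truth


# ---------------------------------------------------------------------------
# GO universes
# ---------------------------------------------------------------------------

def simulate_go_universe(
    n_genes: int,
    term_sizes: list[int],
    seed: int = 0,
    gene_names: list[str] | None = None,
) -> tuple[dict[str, set[str]], dict[str, str]]:
    """Random flat GO annotation: term i gets exactly ``term_sizes[i]``
    distinct genes drawn from the universe.  Returns (term -> gene set,
    term -> readable name)."""
    if gene_names is None:
        gene_names = [f"gene{i:05d}" for i in range(n_genes)]
    if len(gene_names) != n_genes:
        raise ValueError("gene_names length != n_genes")
    rng = np.random.default_rng(seed)
    genes = np.asarray(gene_names, dtype=object)
    terms: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    for i, size in enumerate(term_sizes):
        if size < 0 or size > n_genes:
            raise ValueError(f"term size {size} impossible for {n_genes} genes")
        term = f"GO:{i + 1:07d}"
        terms[term] = set(rng.choice(genes, size=size, replace=False)) if size else set()
        names[term] = f"simulated process {i + 1}"
    return terms, names
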