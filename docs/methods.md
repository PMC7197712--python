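# Methods

`heartregen` re-implements, as a tested and reusable pipeline, the
computational analysis used in transgene-reporter single-cell studies of
zebrafish heart regeneration: droplet scRNA-seq quality control, reporter
gating, clustering, differential expression with GO enrichment, and the
histological wound-quantification formulas. Every stage can be exercised
without any external download because a synthetic-data generator plants
ground truth with the statistical structure the analysis assumes.

## The data model

A `CountMatrix` holds a sparse cells-by-features UMI table whose feature
space contains ordinary genes, mitochondrial genes (recognised by a
configurable name prefix, default `mt-`), and ten transgene sequence
contents: the three mCherry plasmid contents (`mCherry`,
`mCherry-plasmid-backbone`, `mCherry-polyA`) and the seven Citrine plasmid
contents (`Citrine-3x-HA-tag`, `Citrine-BirA`, `Citrine-Tav-2a`, `Citrine`,
`Citrine-polyA`, `Citrine-Frt1`, `Citrine-Remaining`). Matrices travel on
disk as 10x-style MatrixMarket triplets (features on rows), with barcodes
carrying a per-cell sample label.

## Synthetic data

The generator emulates the study design, not the biology:

* **Expression.** Gene g in a cell of type t draws NB(mu_{t,g}, d) with
  variance mu + d mu^2 (d = 0.3 in the study-like default config). Each
  population's mean vector is a shared lognormal baseline with a
  population-specific block of markers set to a flat elevated mean,
  rescaled to a common expected library size (2,500 UMIs by default).
  A flat block rather than a multiplied baseline is used deliberately: a
  multiplied lognormal tail pushes marker genes past the abundance window
  of HVG selection (see below), which silently deletes the discriminative
  genes — a failure mode we measured, not a hypothetical.
* **Reporters.** Transgene features are Poisson conditioned on the cell's
  true reporter status; reporter-negative states default to rate 0. An
  optional `guaranteed_reporter_umi` mode floors the canonical feature of
  positive cells at 1 UMI ("noiseless emission"), making gating truth
  exactly recoverable.
* **Doublets** are exact element-wise sums of two sampled singlet
  profiles; the truth table records both parents, so conservation is
  testable bit-for-bit.
* **Low-quality cells** express fewer than 100 features by construction;
  every ordinary singlet is topped up to at least 100 expressed features,
  so the min-genes filter separates the two classes exactly. With
  singlet count S and fractions f_d, f_lq, the emitted total is
  T = S/(1 − f_d − f_lq), so e.g. 1,750 singlets with f_d = 0.10 and
  f_lq = 0.025 emit exactly 2,000 barcodes (200 doublets, 50 low-quality).
* **Condition structure.** The study-like default config has three samples
  (uninjured wild type, injured wild type, injured runx1 mutant) and seven
  populations; the injury-specific endocardial population is absent from
  the uninjured sample, and the thrombocyte and myofibroblast populations
  are absent or strongly depleted in the mutant — the composition shift the
  downstream tables are meant to expose. Defaults target post-QC scale
  (thousands of cells per sample); capture loss and sequencing saturation
  are not modelled.
* **Histology.** AFOG-like images paint a disk-shaped wound whose pixels
  are fibrin-red (0.95, 0.15, 0.15), collagen-blue (0.20, 0.30, 0.85) or
  other-orange (0.45, 0.30, 0.10) in requested area fractions
  (largest-remainder apportionment, exact to one pixel), plus optional
  Gaussian pixel noise. The palette keeps every discriminating channel
  at least 3 noise SDs (at sd 0.05) away from the default 0.6 thresholds.
  Nuclei tables flag Mef2/PCNA per nucleus with border/remote zones and a
  planted double-positive fraction.

What passing tests on this generator do *not* show: robustness to ambient
RNA, batch effects, saturation, cell-cycle structure, or continuous
differentiation trajectories — none of which the generator emulates.

## Quality control

The filtering order is fixed: (1) remove cells expressing fewer than 100
features (strictly fewer — a cell at exactly 100 is retained); (2) score
and remove doublets; (3) drop undetected genes; (4) normalise each cell to
10,000 total counts and apply natural log1p. Per-sample bookkeeping
(retained = passed − removed) is an exact integer identity.

The doublet scorer is written from scratch: simulated doublets (2 per
observed cell by default) are sums of random observed raw profiles; both
sets are log-normalised, restricted to HVGs, z-scaled with observed-cell
statistics, and projected onto the observed cells' first 30 PCs. For each
cell, with m simulated points among its k = 30 nearest neighbours, the
smoothed fraction q = (m+1)/(k+2) is converted to the posterior doublet
probability given a prior expected doublet rate rho (default 0.06, a
typical droplet loading rate):

    score = (q rho / r) / (1 − rho − q (1 − rho − rho / r))

where r is the simulated:observed ratio. A cell whose neighbourhood
mirrors the global mix scores ~rho and a cell surrounded by simulated
doublets scores ~1, which is what makes fixed thresholds in the 0.27–0.38
range meaningful: the naive rescaled neighbour fraction (without the
prior) maps a *null* neighbourhood to 0.5 and would remove roughly half of
all singlets at those thresholds. Homotypic doublets are intrinsically
invisible to any expression-based scorer once library size is normalised
away; detection power therefore comes from heterotypic pairs, and AUROC
against planted truth exceeds 0.9 whenever several populations are
present.

## Gating

Reporter calls are made on raw counts, before any normalisation. A cell is
mChr+ with ≥1 UMI summed over the three mCherry contents, Cit+ with ≥1 UMI
over `Citrine`, `Citrine-polyA`, `Citrine-Remaining` (the other four
Citrine contents are carried but never confer positivity), kdrl+/runx1+
with ≥1 UMI in the endogenous gene. Composite gates are unions —
kdrl+mChr+ = kdrl+ OR mChr+, runx1+Cit+ = runx1+ OR Cit+ — and double+ is
their intersection, so double+ ⊆ both unions on every input and adding
UMIs can never turn a flag off. Population percentages are of retained
cells per sample (whether the original tables used retained cells or all
barcodes is not stated; retained is the default here and the denominator
is explicit in the output).

## Clustering

* **HVG selection** works on log-normalised data: per-gene mean mu and
  dispersion d = var/mu of the back-transformed (expm1) values, genes
  binned into 20 equal-width bins of log1p(mu), d z-scored within each bin
  (ddof = 1; bins with one gene or zero spread get normalised dispersion
  0), and a gene is highly variable iff 0.0125 < log1p(mu) < 4 and its
  normalised dispersion is ≥ 0.5. Raising `min_disp` can only remove
  genes (monotone).
* **Regression/scaling.** Total counts and percent-mitochondrial UMIs
  (computed from the raw matrix) are regressed out gene-wise by least
  squares with intercept; residuals are zero-centred and scaled to unit
  variance (zero-variance genes become zero columns). Because the
  operation is per-gene, it is applied to the HVG subset only — identical
  to regressing everything and then subsetting, at a fraction of the
  memory.
* **PCA** takes the first 50 components (full SVD below 1,000 cells,
  seeded randomised solver above), ordered by explained variance, each
  component sign-fixed so its largest-magnitude loading is positive —
  cluster labels must be reproducible, and sign-indeterminate scores are
  the usual way they fail to be.
* **kNN graph**: k = 10 Euclidean neighbours per cell, self excluded,
  union-symmetrised, uniform edge weights.
* **Louvain** modularity clustering at a per-analysis resolution (1.0 for
  all cells; 0.5, 0.6, 0.7 for the cardiomyocyte and double-positive
  subsets). The node-visit randomness is seeded and labels are relabelled
  in decreasing cluster size, so runs are deterministic. The pipeline
  reports however many clusters Louvain yields.
* **UMAP** is library-backed, fed the package's own kNN graph as a
  precomputed neighbour set, seeded; the contract is determinism and
  finite coordinates, not layout details.
* **Subset re-clustering** reruns the entire chain (including gene
  pruning and HVG selection) on the subset.

## Differential expression and GO

Marker ranking uses the variance-overestimating two-sample t statistic:

    t_g = (mu_group − mu_rest) / sqrt(s2_group/n_group + s2_rest/n_group)

— the rest variance is divided by the *group* size, inflating the
denominator whenever the group is smaller, hence |t_overestim| ≤ |t_welch|
there. The Welch–Satterthwaite degrees of freedom use the same
substitution (both inner denominators n_group − 1). P values are
two-sided; zero-denominator genes get t = 0, p = 1; BH correction is the
standard step-up with a running minimum, clipped at 1. Under permuted
labels the test is conservative (measured pooled false-positive rate
~0.03 at nominal 0.05).

GO enrichment takes the top 50 ranked genes (ties at the boundary broken
by gene name), restricts each flat term set to the universe, keeps terms
with more than five and fewer than 500 genes, computes the one-sided
hypergeometric tail P(X ≥ k), and BH-corrects across surviving terms. The
universe defaults to all genes retained after QC pruning (whether the
original analysis used annotated or detected genes is unstated). No
ancestor-term propagation is performed.

## Dotplot statistics and composition

Two scalings, matching the two figure styles: *max-scaled* divides each
gene's group means (and expressing-cell counts) by their maximum over
groups, 0 when the maximum is 0; *min-max* subtracts the per-gene minimum
over groups and divides by the maximum of the min-subtracted values, with
dot size as the plain expressing fraction. When every group mean is equal
the min-max statistic is defined as 0 (range-zero convention), and an
alternative divisor (maximum of the original means) is available behind a
flag since the verbal description admits both readings. "Expressing"
means raw count > 0 everywhere. Cluster-by-sample tables are exhaustive
cross-tabulations.

## Histomorphometry

* **Open-wall %** = 100 × max(open compact-myocardium length) /
  max(ventricle perimeter), the maxima taken *independently* across a
  fish's sections — exactly as the measurement protocol reads, even though
  a matched-section ratio would also be defensible; `matched_sections=True`
  provides that alternative (ratio on the largest-perimeter section).
* **Wound-area %** = 100 × max(wound area) / max(ventricle area), same
  convention.
* **AFOG composition**: within the wound mask, a pixel is red when its
  red channel exceeds the red threshold and blue likewise; a pixel
  exceeding both goes to the larger excess (ties to red), making the
  classes disjoint; orange is the exact complement so the three
  percentages sum to 100.0 in floating point. Thresholds are mandatory
  experiment-wide settings; the 0.6/0.6 defaults are arbitrary mid-range
  values. On noise-free planted images recovery is exact to pixel
  rounding; at Gaussian noise sd 0.05 it stays within ±3 percentage
  points by palette design.
* **Proliferation index** = 100 × (PCNA+ ∧ Mef2+)/Mef2+ within a zone,
  pooled over a fish's sections (a per-section-mean alternative is a
  flag); fewer than three sections warns, zero Mef2+ nuclei is an error.
  On synthetic tables the border zone is a label; the anatomical
  definition (cardiomyocytes closest to the wound) has no metric analogue
  here.

## Problem sizes and numerical choices

Tests and the acceptance script run the generator at reduced scale — QC
recovery on 2,000 barcodes (50 planted low-quality, 10% doublets),
clustering recovery on 4 types × 300 cells over five seeds (separation
calibrated so the planted types clear a 0.5 silhouette in PCA space),
normalisation identity on 20 random fixtures, DE null calibration at 500
permutations, AFOG on 200×200 images — sizes chosen so each property is
measured with comfortable statistical margin while the whole suite stays
fast. The CLI determinism check runs the simulate → qc → gate → cluster
chain twice and compares every output file byte for byte.

Floating-point conventions: sample variances use ddof = 1 throughout;
normalisation and gating never mutate the raw matrix; all randomness flows
through explicit integer seeds (NumPy `default_rng`; the Louvain step
seeds the `random` module state that backs igraph and restores it after).

## Known limitations

Real thresholds (doublet cut-offs, AFOG channel settings) are
study-specific calibrations, taken as configuration here and not
re-derived. The published headline numbers (per-sample QC tallies, HVG
counts, 26–27 clusters, AFOG scar percentages, FACS fold-changes) derive
from sequencing and histology raw data that are not redistributable and
are therefore not reproduced; the package instead proves each formula and
procedure against planted ground truth. Homotypic doublets are
undetectable by construction of any expression-only scorer. The GO test
treats terms as flat sets; analyses needing the ontology graph should
propagate annotations before calling it.
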