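# heartregen

Reporter-aware single-cell analysis and wound histomorphometry for
zebrafish heart-regeneration studies.

After cryoinjury, zebrafish ventricles regenerate: the wound (fibrin and
collagen, visualised by AFOG trichrome staining) is progressively replaced
by new myocardium, with injury-activated endocardium, thrombocytes and
myofibroblasts shaping the scar. Studies of this process combine droplet
scRNA-seq of hearts carrying two fluorescent reporter transgenes
(kdrl:mCherry marking endocardium/endothelium, runx1:Citrine marking
injury-responsive cells) with section-level quantification of wound
composition and cardiomyocyte proliferation. `heartregen` implements that
computational stack as a tested library + CLI, and ships a synthetic-data
generator that plants ground truth for every stage, so the whole pipeline
is exercisable and verifiable without any sequencing download.

## What it computes

* **QC** — cells expressing < 100 features are removed; doublets are scored
  by a from-scratch simulated-doublet kNN classifier (synthetic doublets =
  sums of random observed profiles, embedded via log-normalise → HVG →
  PCA; score = posterior doublet probability given the neighbour fraction,
  calibrated by the simulated:observed ratio and an expected doublet-rate
  prior) and removed above a per-sample threshold; counts are normalised
  to 10,000 per cell and natural-log1p transformed.
* **Reporter gating** — on raw counts, mChr+ (≥1 UMI over the three mCherry
  plasmid contents), Cit+ (≥1 UMI over Citrine, Citrine-polyA,
  Citrine-Remaining), kdrl+, runx1+; unions kdrl+mChr+ and runx1+Cit+, and
  double+ as their intersection; population count/percentage tables per
  sample.
* **Clustering** — dispersion-binned HVG selection
  (min_mean 0.0125, max_mean 4, min_disp 0.5, 20 bins), regression of
  total counts and %-mito, unit scaling, 50-PC PCA, k = 10 kNN graph,
  Louvain at per-analysis resolution (1 / 0.5 / 0.6 / 0.7), seeded UMAP,
  and subset re-clustering.
* **Differential expression** — the variance-overestimating t test
  t = (μ_g − μ_r)/√(s²_g/n_g + s²_r/n_g) with the Welch–Satterthwaite df
  under the same substitution, BH correction; GO enrichment by the
  hypergeometric tail on the top 50 genes over terms with 5 < K < 500.
* **Composition / dotplot statistics** — cluster×sample tables and the two
  dotplot scalings (max-scaled and min-max).
* **Histomorphometry** — open-wall % and wound-area % from per-fish section
  maxima, AFOG red/blue/orange decomposition by channel thresholding
  (orange = remainder, the three sum to exactly 100), the PCNA⁺Mef2⁺/Mef2⁺
  proliferation index, and in/away-from-wound double⁺ cell counts.

## Worked example

```python
from heartregen import sim, qc, gating, cluster

cfg = sim.default_config(n_genes=1000, scale=0.2, seed=0)   # 3 samples
matrix, truth = sim.simulate_dataset(cfg)

passed, low = qc.filter_low_gene_cells(matrix, min_genes=100)
scores = qc.score_doublets(passed, qc.QCConfig(seed=0))
retained, doub = qc.apply_doublet_filter(passed, scores, 0.3)
print(f"{matrix.n_cells} barcodes -> {passed.n_cells} passed -> "
      f"{retained.n_cells} retained "
      f"({len(low)} low-complexity, {len(doub)} doublets removed)")

flags = gating.classify_cells(retained)
print(gating.tabulate_populations(flags, retained.samples).round(1))

res = cluster.run_cluster_pipeline(retained, cluster.ClusterConfig(seed=0),
                                   with_umap=False)
print("clusters:", res.n_clusters)
```

prints

```
2886 barcodes -> 2827 passed -> 2687 retained (59 low-complexity, 140 doublets removed)
sample     wt_uninjured       wt_3dpci       runx1_3dpci
stat              count   pct    count   pct       count   pct
population
mChr+               295  36.4      428  42.2         459  53.3
Cit+                123  15.2      318  31.3         172  20.0
kdrl+               296  36.5      411  40.5         430  49.9
runx1+              103  12.7      253  24.9         120  13.9
kdrl+mChr+          317  39.1      461  45.4         485  56.3
runx1+Cit+          125  15.4      331  32.6         177  20.6
double+               4   0.5      148  14.6         168  19.5
clusters: 7
```

The gating table is the marker-based population summary: nearly all
double-positive cells appear only after injury (0.5% uninjured vs ~15–20%
at 3 days post-cryoinjury), and the cluster×sample table from `res.counts`
shows the planted composition shifts — an injury-only endocardial cluster
present in both injured samples and a thrombocyte cluster absent from the
runx1-mutant sample.

The same stages are available as a CLI (`heartregen simulate / qc / gate /
cluster / de / go / dotplot-stats / histo`), reading and writing 10x-style
MTX triplets and TSV reports; a fixed `--seed` reproduces every output
byte for byte.

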