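# Methods

## Synthetic cohort model

The generator emulates a 14-patient head-and-neck cancer CTC study plus six
healthy donors. Each stained sample is a mixture of:

- **carrier PBMCs** (default 9,000 events) barcoded on Cd-106;
- **osmium-labelled control PBMCs** (default 1,000) with stimulated
  phospho-signalling;
- the **enriched fraction** (default 1,000): the patient's true CTCs plus
  contaminating leucocytes;
- **debris/doublets** (default 5 % of events) with aberrant acquisition
  parameters.

Carrier and control populations are scaled down ~100× from the study's
900,000 / 100,000 cells to keep desk-scale runtimes; their 9:1 ratio is
preserved. The enriched fraction is fixed at 1,000 events (the study's
20,000–50,000, scaled) so that the largest patient total (218 CTCs) fits.
Per-patient CTC totals are the cohort table's printed values (sum 1144);
the generator also exposes the alternate reading of patient 12 (4 rather
than 0 cells) that appears in the running text. Two healthy donors carry 2
and 3 background CTC-like cells per draw (panCK-moderate, CD45-low,
simulated from the epithelial archetype); the wording "cells/ml" versus
per-draw totals is ambiguous in the source material, and per-draw totals
are used.

**Intensity model.** Each (population, marker) channel is a zero-inflated
lognormal: zero with probability `zero_p`, otherwise
`LogNormal(log(c·sinh(t)), σ)` with cofactor `c = 5` and σ = 0.35, so the
ArcSinh-transformed median equals the configured level `t`. This is a
standard lightweight surrogate for ion-count statistics; it reproduces the
right scale, skew and zero mass of CyTOF channels but not isotopic
spillover, acquisition drift or cell-size covariation (the package's
non-goals). `GeneratorParams.expected_arcsinh_mean` evaluates the model's
exact transformed mean by Gauss–Hermite quadrature; the moment-fidelity
tests compare simulated means against it.

**Archetypes.** Three CTC archetypes encode the study's qualitative
co-patterns: epithelial (panCK/EpCAM/E-cadherin high, vimentin low,
CD133/CD24 and checkpoint markers elevated, pSTAT1/3/5, pPARP, pAKT
elevated), early-EMT (vimentin high, EpCAM/E-cadherin moderate,
Twist/CD44/pERK/pCREB elevated) and advanced-EMT (vimentin high,
EpCAM/E-cadherin low, Snail1 elevated, Ki-67 and pSTAT1 low, pCREB
elevated). Pan-cytokeratin carries no zero inflation in CTC archetypes
because the identification rule defines CTCs as panCK-positive. Default
per-patient mixtures over the three archetypes were fixed so the expected
cohort-level composition matches the reported ~18.7 / 50 / 31.3 % split,
with two patients (10 and 11) lacking one subgroup each as reported.

**Acquisition parameters.** Intact singlets draw Gaussian
Center/Offset/Width/Residual/Event_length values; debris inflates Residual
and Offset and broadens Width. The debris generator is intentionally
separable so truth-label agreement of the clean-up gate is a meaningful
metric.

**Determinism.** Every output is a pure function of (config, params,
seed); per-sample streams derive from `SeedSequence([seed, stable_id])`.

## Gating

- **ArcSinh cofactor 5** — the mass-cytometry convention; configurable. A
  `transformed` flag forbids double transformation.
- **Clean-up windows** default to Tukey fences `Q1 − 3·IQR … Q3 + 3·IQR`
  per acquisition channel. Plain central-quantile windows are also
  available, but a quantile window can by construction remove at most its
  tail mass per channel (≈1 % at the 99th percentile), far less than a
  realistic debris fraction; the Tukey fence adapts to the intact mode
  while excluding a contaminating mode of any size. Fixed bounds can be
  supplied for full reproducibility.
- **Deconvolution and marker cuts** are valley-seeking: a Gaussian KDE of
  the channel's ArcSinh values, the two dominant modes, and the density
  minimum between them. The CTC-rule cuts pool enriched events with the
  carrier PBMCs as an anchor for the marker-positive mode. Unimodal
  channels fall back to a configured fixed cut (default 2.0 on the ArcSinh
  scale); with no fallback configured, deconvolution refuses.
- **Positivity**: negative iff the tally ≤ 4 cells per draw, the background
  threshold fixed by the healthy-donor data. Per-ml concentration is
  round-half-up of total/9 ml, which reproduces the printed 2–24 cells/ml
  range from totals 18 and 218.
- A single lower pan-cytokeratin cut is used; "intermediate to high" is not
  given an upper bound.

## Clustering

- **Batch SOM**, default 10×10 grid, 10 epochs, Gaussian neighbourhood
  whose radius shrinks linearly from max(grid)/2 to 0.5; codebook
  initialized from a seeded random sample of events. The recorded
  quantization-error series starts with the pre-training error of that
  init, which for well-separated data can be lower than the error after the
  first wide-radius smoothing epoch; the training contract is that the
  final error does not exceed the epoch-1 error.
- **Elbow metaclustering**: Ward linkage over the codebook; for each k the
  within-metacluster sum of squares WSS(k) of the nested partition; the
  chosen k is the smallest whose incremental decrease WSS(k) − WSS(k+1),
  **relative to the total sum of squares WSS(1)**, falls below 0.05.
  Normalizing by WSS(1) rather than by the total decrease keeps the rule
  well-defined when the codebook has a single centre (the curve is then
  flat relative to overall scatter and the smallest k is kept).
- **Parent groups**: average-linkage euclidean tree over metacluster median
  profiles, cut at exactly 3 (configurable), because the analysis targets
  the three-subgroup EMT structure. Labels follow the marker definition:
  lowest mean vimentin → epithelial; of the rest, higher mean
  EpCAM/E-cadherin → early-EMT. Exact ties are reported as errors, never
  silently broken.
- Clustering uses all 40 analytical markers on the ArcSinh scale with no
  further per-marker scaling (cytometry convention); a z-scaling flag is
  available. Metaclustering is a single agglomerative pass; consensus
  resampling is out of scope.
- The t-SNE embedding is plotting plumbing only; nothing downstream
  consumes it.

## Statistics

- **Mann–Whitney U**: exact two-sided p by full enumeration of label
  assignments for pooled sizes ≤ 12 (ties handled as a permutation null);
  otherwise midranks with tie-corrected variance, continuity correction and
  a normal reference. Subgroup contrasts default to event-level ArcSinh
  intensities; per-cluster medians (the published unit) are supported via
  the same interface when a cluster-level comparison is wanted. Raw p
  values are reported by default; Benjamini–Hochberg is opt-in.
- **Composition PCA**: centred PCA of the patients × metaclusters fraction
  matrix; patient groups by k-means on the scores with k chosen by mean
  silhouette over 2–6. The grouping rule is an explicit stand-in for what
  was originally a visual grouping.
- **Clinical associations**: univariate logistic regressions (Wald p) of
  T-stage ≥ 3, nodal positivity and stage III/IV on CTC count; Welch
  t-test of the per-patient EMT fraction by nodal status (the source does
  not say Welch or Student; Welch is the safer default); one-way ANOVA of
  CTC count across tumour classes. Perfect or quasi-separation in a
  logistic fit is flagged (`converged: False`), not raised.

## Expression comparators

- **Normalization**: median-of-ratios size factors computed on genes
  nonzero in every sample, standardized to geometric mean 1 (making the
  operation idempotent).
- **NB Wald test**: per-gene method-of-moments dispersion pooled over
  groups, floored at 1e-8, and shrunk geometrically (weight 0.5) toward the
  gene-wise median; Wald statistic from the delta-method SE of the log2
  fold change of normalized means; reference distribution a moderated t
  with `n1 + n2 − 2 + 6` degrees of freedom, reflecting the information the
  cross-gene prior adds. This choice keeps the null calibrated (type-I
  error near nominal, p approximately uniform) while retaining power at
  n = 3 vs 3. Full dispersion-trend shrinkage and independent filtering of
  the reference RNA-seq tool are deliberately out of scope. For the
  1-vs-1 paired enriched/PBMC design the per-gene dispersion is
  inestimable and a configured prior (default 0.05) is used.
- **Bulk sensitivity model**: a panel-marker gene's mean in a sample is
  `noise_floor + scale · (fraction of cells expressing the protein)`
  (defaults 3 and 4000, NB dispersion 0.05). Epithelial transcripts are
  absent from blood, so even modest CTC loads clear the floor, while a
  handful of EMT CTCs among ~1000 enriched cells does not — the mechanism
  behind bulk profiling missing low-frequency EMT populations. The
  marker→gene map is a packaged editable table; pan-cytokeratin maps to
  KRT19 as a flagged representative and phospho-epitopes map to no gene.
- **Tumour classification**: log1p of normalized signature counts, z-scored
  per gene, euclidean complete-linkage tree cut at 3; a branch is *mixed*
  when its mean epithelial and mesenchymal z-scores are both above 0,
  otherwise it takes the higher-scoring arm. The published EMT gene list is
  not available, so the synthetic signature uses 25 + 25 placeholder gene
  identifiers; mixed-class samples co-express both arms at a moderately
  high level, which is what makes the both-above-zero rule identifiable.
- The DGE significance threshold for the panel map is FDR 0.05 (the source
  figure does not state one).

## What passing tests do and do not show

The generator reproduces the *structure* of the study — population ratios,
marker co-patterns, count scales, debris geometry, the bulk detectability
mechanism — with ground truth attached, so tests demonstrate that the
pipeline recovers what the generator encodes (tallies within ±2 cells,
subgroup ARI ≥ 0.8, directional contrasts, class recovery). They do not
demonstrate performance on real instrument data, which adds spillover,
drift, staining batch effects and biological variance the model omits; the
published per-patient concordance figures (e.g. 8/10 bulk agreement)
depend on undeposited data and are covered only by the corresponding
mechanism properties.

## Problem sizes

Default desk-scale runs: ~11,500 events × 47 channels per sample, 20
samples per cohort (~230k events through gating), 1,144 concatenated CTCs
through a 100-node SOM, 600-gene null calibrations and ≤ 100-gene DE
panels. A full pipeline run completes in ~15 s on one CPU; the test suite
in under a minute.
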