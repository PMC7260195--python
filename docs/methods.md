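# Methods

## Scope and design

`cytogate` implements a hybrid automated/manual immunophenotyping
workflow: automated hierarchical gating from a text template, k-means
subset calling where 2D gates are insufficient, batch review-image
generation with a tag store, routing of flagged samples to manual
re-gating, and the statistics used to decide whether the automated
arm agrees with a manual gold standard. Interactive review is out of
scope by design: the annotation store is a plain CSV any tool can
edit, and the "manual" arm of the workflow stays manual — the package
only exports the hand-off list and per-sample gate geometry (JSON).

## Event I/O and transforms

FCS reading supports list-mode 3.0/3.1 with float (`$DATATYPE F`/`D`)
and byte-aligned unsigned-integer data; channel names prefer `$PnS`
over `$PnN`. Writing emits FCS 3.1 little-endian float32, which is
lossless for fixture round-trips at float32 precision. Rows containing
NaN are dropped and counted, never imputed; all counts are defined
over retained events.

Density gating assumes a roughly Gaussian-mixture geometry, which raw
fluorescence does not have; the default transform is arcsinh with
cofactor 150 (a common choice for conventional cytometers),
configurable per channel. A logicle transform is available, computed
by numerically inverting the Parks–Moore biexponential on a dense
grid (strictly monotone by construction; inversion error far below
display resolution). Scatter channels (FSC*/SSC*) and Time stay
linear unless explicitly listed. Gate ranges in templates are
expressed in transformed units.

## Density gates

`mindensity` fits a Gaussian KDE (Silverman bandwidth unless
overridden) on the parent's events restricted to `gate_range`,
evaluated on a 512-point grid. Local maxima with height ≥
`min_peak_height` × the global maximum count as peaks (boundary maxima
included, since a mode clipped by `gate_range` is still a mode). With
≥ 2 peaks the cut is the density minimum between the two tallest
(ties: leftmost pair, then leftmost valley — determinism over
elegance); with one peak the cut sits where density decays to
`min_peak_height` × peak height on the side selected by `sign`. The
default `min_peak_height` of 0.05 suits roughly balanced mixtures;
gates that must detect a small population (e.g. a 2% dead-cell mode)
need a lower threshold in the template — the shipped full template
uses 0.01 for the viability gate.

`quadrant` applies two independent 1D cuts; "+" is strictly above the
cut, so the four sign pairs partition the parent exactly (no dead
zone). `singlet` fits `FSC-H ≈ β·FSC-A` with β = median(H/A) and
keeps events within `band_k` σ-consistent MADs (1.4826 × raw MAD) of
the residual; the default `band_k = 4` is a ≈4σ band under Gaussian
noise (≥ 99.99% singlet retention) while doublets, whose height is
≈ 0.6 of additive, sit far outside it.

Any gate needs ≥ 20 parent events (configurable); below that the
population is tagged `low_cell_count`. A failed gate tags its subtree
`needs_manual_refinement` and the rest of the sample proceeds — the
flag, not an exception, is the hand-off signal.

## k-means subset caller

Input is the pooled CD4⁺+CD8⁺ events on (CCR7, CD45RA, CD28),
clustered jointly and split by parent afterwards (a per-parent mode
exists as an option). Markers are z-scored (ddof = 1) for clustering
only; cluster medians for ±-labelling are taken on unscaled values
(monotone scaling cannot change median ranks, so this is
observationally equivalent — documented for clarity). k-means uses
Lloyd's algorithm, k = 4, k-means++ initialization, 10 restarts,
tolerance 1e-6, max 300 iterations, seeded — identical input and seed
give identical assignments. Ranking ties in the median split break by
cluster size (larger first) then cluster id, so the 2/2 split per
marker is always exact and deterministic.

Subset identity keys on (CCR7, CD45RA): (+,+) naive, (+,−) central
memory, (−,−) effector memory, (−,+) effector. CD28 is the secondary
check: every targeted triple constrains it (naive/central memory
CD28⁺, effector memory/effector CD28⁻), and by default a cluster
whose CD28 sign contradicts its target counts as unmappable and flags
the sample, exactly like a non-bijective (CCR7, CD45RA) assignment.
This matters for the flag's diagnostic value: because the forced 2/2
median split almost always produces a (CCR7, CD45RA) bijection even
on structureless data (k-means centroids arrange near-tetrahedrally,
and the three 2+2 partitions of a tetrahedron are mutually
orthogonal), the bijection test alone would almost never fire. With
the full-triple rule the measured flag rate is ~100% at zero marker
separation, ~75% at 1σ, and ~0% at 6σ — the flag fires on hard
samples and stays quiet on easy ones. A warn-only CD28 mode
(`cd28_strict=False`) is available. Flagged samples still return
counts; the eight per-parent outputs always partition the input
events exactly.

A fourth marker or automatic selection of k is deliberately not
attempted.

## Validation battery

- **Pearson r** with a Fisher-z 95% CI (SE = 1/√(n−3)); needs n ≥ 4
  and non-constant columns.
- **Percent bias** is the ratio of means, robust to the near-zero
  per-sample denominators of rare subsets; the mean of per-sample
  ratios is available behind a flag. The 95% CI is a seeded
  nonparametric bootstrap over paired rows (2000 resamples).
- **F-measure** `2TP/(2TP+FP+FN)` over event masks on a shared event
  index; both-empty is defined as F = 1 (and logged) so that perfect
  agreement on an absent population is not penalised.
- **Outlier screening** removes a pair when *either* method's value is
  more than 3 SD from that method's own mean, in a single pass
  (no re-iteration); correlations are reported before and after.
- **Optimization rule**: strictly r > 0.75 passes; r = 0.75 fails.
- **ICC**: REML mixed model with control fixed effects and a random
  technician intercept (statsmodels MixedLM); inter-technician
  variance is the technician component, intra-technician the
  residual. Variance estimates are floored at 0 before forming
  ICC = σ²inter/(σ²inter+σ²intra); near-zero components are expected
  and legitimate. On balanced crossed designs the REML components
  agree with the ANOVA method-of-moments estimator (tested within 10%
  relative).

One estimation subtlety: with few technicians the per-dataset ICC
ratio is Jensen-biased downward even when both variance components
are estimated almost without bias (the ratio is concave in the
inter-technician component; with 5 technicians and equal components
of 0.5 the mean per-dataset ICC is ≈ 0.44 for REML and
method-of-moments alike). When pooling replicated designs the package
therefore aggregates variance components first — components pool
linearly, ratios do not — and the pooled ICC recovers the true value
(0.50 ± 0.01 over 200 replications in the acceptance run).

## Synthetic data

The generator emulates the statistical structure the pipeline relies
on, not the instrument physics. Populations are multivariate
Gaussians in transformed units: marker-negative N(0, 0.5²),
marker-positive N(4, 0.5²) — 8 component SDs between modes, so
density valleys are unambiguous. The default panel places typical
peripheral-blood fractions on a lymphocyte/monocyte/dendritic tree
with T/B/NK lineages and the eight T-cell subsets
(naive/CM/EM/effector at 0.40/0.25/0.25/0.10 of each parent).
FSC-H is 0.98 × FSC-A plus noise for singlets; doublets sum scatter
with FSC-H × 0.6 sub-additivity (a conventional caricature) and take
the elementwise max of fluorescence; dead cells get a
viability-dye-positive signal. Defaults: 20,000 events per sample
(a typical per-file inclusion floor), 5% doublets, 2% dead.

The T-cell harness draws each subset as a unit-SD Gaussian at
± separation/2 per signed marker dimension, so `separation` is the
mode distance in component SDs; 6 is an easy sample, 0 a
structureless one. Paired-count and technician-design generators
embed a known multiplicative bias and known variance components
(mean-one lognormal noise; balanced 8 controls × 5 technicians × 4
replicates) so the statistics can be checked as estimators.

What the generator does *not* model — spectral spillover,
autofluorescence, instrument drift, heavy-tailed debris, correlated
marker noise — bounds what passing tests show: they validate the
algorithms against their stated assumptions, not performance on any
particular instrument's files.

## Problem sizes and determinism

The test and acceptance runs use 100 simulated samples × 20,000
T-cell events for subset recovery, one 20,000-event sample for gating
equivalence, 500 paired samples for bias recovery, 200 + 100
technician designs for the ICC, and 1000 random mask pairs for the
F-measure identity — sizes at which the binomial/REML sampling error
is comfortably below the asserted tolerances. Every stochastic step
takes an explicit seed, and identical inputs give bit-identical gate
geometry, counts and assignments.

## Known limitations

- 1D/rectangular/quadrant geometry only; no ellipsoid or curved
  gates, no FlowJo workspace round-trip (gate export is JSON).
- Events are assumed compensated; no spillover estimation.
- The density-cut heuristics (grid, bandwidth, shoulder rule) are
  deliberately simple; pathological multimodality beyond two modes in
  `gate_range` resolves by the two-tallest-peaks rule, which may not
  match an analyst's intent.
- The shipped panel templates are reconstructions for the synthetic
  panel, not a validated clinical strategy.
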