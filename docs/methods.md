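# Methods

This note records the model behind `molstage`, the choices made where
the procedure was genuinely open, and what the synthetic benchmarks do
and do not demonstrate.

## Data model

Expression is replicate-level, non-negative, RPKM-like: `x[j, r, i]` for
condition *j* (one cultivar × vintage × timepoint combination),
replicate *r* and gene *i*.  Conditions within a cultivar × vintage
series carry ordinal timepoints 1, 2, … (contiguity is enforced at
load).  The ordinal index — not the calendar day — is the smoothing
predictor by default: series are sampled at roughly even intervals, and
using the ordinal keeps the scale a function of sampling succession
rather than of one season's calendar.  DOY can be substituted via
configuration.

## Screening

The whole-core-set screen applies four filter families in a fixed order
(a→d), each gene keeping the tag of the first filter it fails, so the
rejection report is deterministic:

| filter | statistic | default |
|---|---|---|
| a. presence | replicate-mean ≥ threshold in ≥ 1 condition of *every* series | 1.0 RPKM |
| b. replicate noise | median over conditions of replicate CV (sample sd / mean; zero-mean conditions excluded) | ≤ 0.8 |
| c. cross-series consistency | minimum pairwise Pearson r of LOESS-smoothed per-series profiles, linearly resampled to a common ordinal grid (10 points) | ≥ 0.6 |
| d. reference congruence (optional) | mean over reference cultivars of Pearson r between the gene's reference stage profile and its training mean profile resampled to the reference's stage count | ≥ 0.5 |

The thresholds are package defaults, exposed in configuration; they are
not published values.  Profiles that are constant up to round-off have
no direction and fail (c).  Filter (d) requires at least three reference
stages — a two-point correlation is ±1 identically and carries no
information.  Genes absent from the reference cannot be evaluated by (d)
and pass through it.

## Smoothing

LOESS with local polynomials of degree 2, tricube weights
`w = (1 − (d/d_max)³)³` on distances scaled by the window's maximum, and
span α = 0.75.  The window holds the ⌈α·n⌉ nearest *points* (replicates
count individually; ties at the window edge are all included) — whether
the span should count points or distinct timepoints is not determined by
the method's description, so the point-count convention was chosen and
fixed.  Because LOESS is linear in the response, the smoother is
materialized as hat rows — one small weighted normal-equation solve per
(series, target timepoint) — and applied to all genes of a series in a
single matrix product; this is what keeps full-transcriptome smoothing
essentially free.  Local fits are solved in the shifted basis
(t − t₀)^p for conditioning.  If the tricube weights leave fewer than
degree + 1 distinct predictors with positive weight (possible in very
short series), the window falls back to uniform weights.  No robustness
iterations are applied.

## PCA and component triage

The conditions × |F| smoothed matrix is column-standardized with
population (n-denominator) moments and decomposed by SVD; explained
variance percentages come from squared singular values.  Each component
is sign-oriented so its scores correlate non-negatively with timepoint
order, making builds reproducible across BLAS implementations.

Components are labelled by effect size: eta-squared of scores against
cultivar, against vintage, and against the timepoint grouping.  The
timepoint grouping (rather than a rank correlation with time) is
essential: the second and third stage components are strongly
stage-dependent but non-monotone in time — the classic horseshoe
geometry of a one-dimensional trajectory in PCA — and a monotone
association measure would mislabel them.  A component is labelled by its
largest effect when it beats the runner-up by ≥ 0.1, else "mixed"; the
three stage-labelled components with the largest explained variance are
selected.  Because many-group eta-squared has a positive noise floor
(≈ (k−1)/(n−1)), small tail components can be labelled "stage"
spuriously; this is harmless for selection (ranking by explained
variance) but the labels of sub-percent components should not be
over-read.  Explicit `pc_indices` always override the triage.

## Bézier curve and marks

The method's description fixes k = 5 control points and 30 evenly
spaced marks but not the fitting algorithm, which is therefore a package
decision, chosen to be deterministic and seed-free: initial parameters
`t_j = (timepoint_j − 1)/(max timepoint of the series − 1)`; control
points by linear least squares on the degree-4 Bernstein basis; then two
rounds of foot-point correction (each condition re-parameterized to its
nearest point on a densely sampled curve, control points re-solved),
keeping the iterate with the smallest summed squared residual.  "Evenly
spaced" is interpreted as equal arc length (the scale is a *linear*
graduation of the curve), computed on a ≥ 10,001-point polyline;
mark parameters are stored so artifact validation can verify marks lie
on the curve to 1e-6.  Scale orientation is fixed by requiring assigned
stages to correlate non-negatively with timepoints (ties broken toward
the first series' first condition), so stage 1 is always the
early-development end.

## Projection

`Z_obs` is column-standardized with the projected dataset's own
means/sds — the dataset-local convention makes projections of a dataset
self-contained but is undefined for a single sample, for which
training-referenced standardization (`standardize="training"`) is
provided.  Full-set projection is `Y = Z̃·A` plus nearest-mark
assignment (Euclidean; ties to the lower stage).  Zero-variance observed
columns are dropped with a warning and treated as unobserved.

Reduced panels impute each component's unobserved genes with the
per-sample average of observed genes of the matching loading sign.  Two
pool conventions are implemented:

* **structured panels** (those produced by `select_reduced_core_sets`)
  carry their component × sign pool memberships, and component *q* is
  imputed from its *own* pools — the genes actually chosen for being
  strongly correlated with *q*;
* **unstructured panels** (arbitrary core-set subsets) fall back to
  splitting all observed genes by the sign of their coefficient in
  `A_q`.

The structured convention is the package's reading of panels built as
"pools of positive and negative loadings of each component".  The
fallback convention, applied to structured panels, measurably attenuates
the estimated coordinates (each component's pool means are diluted by
genes selected for the other components; observed regression slopes
0.75–0.94 on synthetic data, inflating stage shifts at the scale's
extremes), which is why the pool-aware rule is the default for panels
that have the structure.  With the full core set observed, imputation is
vacuous and both paths equal `project_full` exactly — asserted in tests.

## Gene selection

GBM variable importances use gradient-boosted regression trees
(squared-error loss, 500 trees, depth 3, learning rate 0.05, subsample
1.0, fixed seed — hyperparameters are package defaults, exposed in
configuration) of replicate-level expression on (cultivar, vintage,
stage), restricted to conditions at stage ≥ 20; importances are
normalized to percentages.  Selection keeps genes with VIMc ≤ the 10th
percentile of VIMc, VIMy ≤ the 20th percentile of VIMy and VIMs ≥ the
20th percentile of VIMs, boundaries inclusive; a Spearman correlation of
expression with stage over the interval confirms monotone association.
The VIMs criterion is implemented as stated (≥ the 20th percentile,
i.e. permissive); all three quantiles are configurable.

Reduced core sets: p-corr is the Pearson correlation between a gene's
standardized smoothed profile and a component's score vector (the term
is used interchangeably with "loading" here; on standardized data the
two have the same sign pattern).  The pooled top-100 genes by
max-|p-corr| are hierarchically clustered (distance 1 − r, average
linkage, cut to exactly 20 clusters).  Pools of 20/10/5/2 genes per
component × sign are filled by descending |p-corr| — cluster size breaks
ties for the large panels (120/60), while the small panels (30/12) take
representatives of distinct clusters to avoid redundant co-expressed
markers; the third component's pools ignore cluster membership (its
correlations are generally weak).  No gene appears twice in a panel.

## Analytics

Stage-progression rate is the finite difference Δstage/Δtime at
interval midpoints; it telescopes exactly to the total stage change.
Growing degree days use base 10 °C (the viticulture standard;
configurable).  Lin's concordance uses population moments and the
McBride bins (< 0.90 poor, [0.90, 0.95) moderate, [0.95, 0.99]
substantial, > 0.99 almost perfect).  Shift statistics report the mean
absolute shift and the median/IQR of signed shifts with
linear-interpolation (type-7) quantiles.  Trait-over-stage trends reuse
the module's LOESS.

## Synthetic data

The generator emulates the training design: 2 cultivars × 3 vintages ×
10–14 timepoints at 7–10-day intervals × 3 replicates.  A latent stage
s ∈ (0, 1) follows a double sigmoid in development days (gentle rise
centered at day 40, scale 12; steep "onset" rise at day 70, scale 5);
vintages shift the calendar by U(−10, 10) days and cultivars by a fixed
6-day lag.  Non-noise genes read s through one of four archetypes
(monotone up/down with power 0.5–2, transient Gaussian peak, sharp
switch), scaled by lognormal baselines (median 20, log-sd 0.8) onto a
0.15–1.0 dynamic range.  Optional cultivar/vintage-affected fractions
(defaults 15 %/10 %) receive guaranteed mean-centered log-scale
contrasts (effect sd × U(0.5, 1.5)) so that "affected" truth labels
always denote a real effect.  Replicates apply mean-preserving
multiplicative lognormal noise (CV 0.15; optionally U-shaped in stage to
mimic higher early/late biological variability).  Noise genes have
i.i.d. lognormal condition means (CV 0.5) — exchangeable, trend-free.
The truth object stores the per-condition latent stage and a planted
rapid-transition window computed as the development-day interval where
the noise-free standardized expression profiles move fastest (speed
≥ 50 % of maximum).

What the generator does *not* emulate: count-level sampling noise,
platform effects between RNA-seq and microarrays, missing replicates,
expression-level (as opposed to time-shift) vintage responses of whole
pathways, and the dense co-expression structure of a real transcriptome
(real berry genes are far more mutually correlated than independent
archetype draws).  Passing benchmarks therefore demonstrate the
machinery's correctness and the method's behavior under its own
assumptions, not performance on any particular organism's data.

## Benchmark design notes

* Panel-degradation concordance is evaluated by projecting the
  *smoothed* condition profiles — the same matrix whose projection
  defines the scale map — with each panel versus the full core set, so
  the comparison isolates the effect of gene reduction.  Projecting raw
  replicate means instead adds replicate noise that a 120-gene panel
  cannot average away and roughly doubles the apparent shift while
  leaving concordance above 0.94.
* The stage-gene selection benchmark plants 10 % confound-free genes
  among strongly confound-driven ones, restricts archetypes to monotone
  profiles (a gene flat over stages 20–30 is unrecoverable by a
  stage-≥-20 analysis regardless of method), and supplies truth-derived
  stages, isolating the importance machinery from scale-construction
  error.
* The stage-rate peak is compared with the planted window on the pooled
  per-series rates.  Finite differences at ~8-day sampling combined
  with LOESS smoothing can displace the measured peak by up to about one
  sampling interval at some seeds; the acceptance script reports the
  continuous offset alongside the indicator.

## Numerical conventions

Population (n-denominator) moments for standardization and Lin's
coefficient; sample (n−1) standard deviation for replicate CVs;
nearest-mark ties resolve to the lower stage; scale artifacts serialize
every float at full precision with a checksummed gene list and a format
version, and round-trip bit-exactly.

## Known limitations

Cross-platform projection is supported only through dataset-local
standardization; no probe mapping, batch correction or cross-platform
normalization is attempted, and stages projected from very small or
single-sample datasets depend on the standardization mode chosen.  The
curve carries no uncertainty estimate.  Screening thresholds are
heuristics to be tuned per dataset.  The eta-squared triage needs
enough timepoints per series (≥ ~8) to separate stage structure from
its noise floor.
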