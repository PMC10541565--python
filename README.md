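# molstage

**Molecular phenology staging of fruit development from time-series
transcriptomes.**

Classical fruit phenology scales (E-L, BBCH) stage development from
visual and compositional traits, which drift with genotype, season and
site.  `molstage` instead reads the stage off the transcriptome: it
builds a *molecular phenology scale* — a 1–30 graduation of fruit
development — from replicate-level bulk RNA-seq time series, and then
places any expression sample (RNA-seq or microarray, whole gene set or a
small qPCR-sized marker panel) onto that scale.  It is written for
researchers who have multi-season developmental expression series (the
motivating system is the grape berry) and want a genotype- and
vintage-robust axis on which to align samples, compare developmental
rates, or pick marker genes.

## The method

Given expression `x_jri` (condition *j* = cultivar × vintage × timepoint,
replicate *r*, gene *i*, RPKM-like units):

1. **Screening** — keep a core set *F* of genes that are expressed in
   every series, have quiet replicates (median CV), behave consistently
   across cultivar × vintage series, and (optionally) agree with an
   independent multi-cultivar reference panel.
2. **Smoothing** — per gene and per series, LOESS (local polynomials of
   degree 2, tricube weights, span α = 0.75; replicates enter as separate
   points) evaluated at each timepoint gives smoothed values `x̄_ji`.
3. **PCA** — column-standardize the conditions × |F| smoothed matrix and
   take the SVD.  Components are triaged by effect size into stage-,
   cultivar- and vintage-associated; the three stage components span a 3-D
   space in which conditions trace the developmental trajectory.
4. **Scale definition** — fit a Bézier curve (k = 5 control points,
   least squares on the Bernstein basis with foot-point refinement)
   through the 3-D score scatter and place 30 marks at equal arc-length
   fractions along it.  Mark *m* is molecular stage *m*; each condition
   is assigned its nearest mark.

**Projection.**  A new sample matrix `Z_obs` is column-standardized and
mapped through the eigenvector matrix *A* (|F| × 3): `Y = Z̃·A`, then
assigned to the nearest mark.  If only a marker panel `I_obs ⊂ F` is
observed, the missing genes of each component are imputed with the
per-sample average of that component's positive- or negative-loading
pool, according to the sign of the missing gene's eigenvector
coefficient.

**Analytics and selection.**  The package also computes ΔMPhS/Δtime
stage-progression rates over DOY/DAF/GDD axes, growing degree days,
Lin's concordance coefficient `ρ_c = 2·cov(x,y)/(var(x)+var(y)+(μ_x−μ_y)²)`
with the McBride interpretation bins, paired shift statistics between
stagings, gradient-boosting variable importances (relative influence of
cultivar, year and stage per gene) with a quantile selection rule for
stage-tracking transcripts, and loading-based reduced core sets of
120/60/30/12 genes.

A fully parameterized synthetic-data generator (`molstage.simulate`)
emulates the training design — 2 cultivars × 3 vintages × 10–14 roughly
weekly timepoints × 3 replicates, a shared double-sigmoid latent
trajectory with per-vintage/cultivar time shifts, archetypal gene
profiles and lognormal replicate noise — with complete ground truth, so
every stage of the pipeline is testable without downloads.

## Worked example

```python
import numpy as np
from scipy.stats import spearmanr
import molstage as ms

tensor, truth = ms.generate_dataset(seed=1)        # 78 conditions x 2000 genes
core, report = ms.screen_genes(tensor)
artifact, model = ms.build_scale(tensor, core)
rho = spearmanr(artifact.training_stages, truth.latent).statistic

from molstage.smoothing import smooth_dataset
smoothed = smooth_dataset(tensor, core)
Zs = (smoothed - artifact.column_means) / artifact.column_sds
scores = Zs.to_numpy() @ artifact.eigenvectors
panels = ms.select_reduced_core_sets(artifact, Zs, scores)
full = ms.project_full(smoothed, artifact)
for size, panel in panels.items():
    red = ms.project_reduced(smoothed[panel.gene_ids], panel, artifact)
    ccc = ms.lin_concordance(red.stage, full.stage)
    print(f"panel {size:>3}: Lin's concordance {ccc:.3f} ({ms.concordance_class(ccc)})")
```

prints

```
screened: 1600 of 2000 genes retained
stage components: [1, 2, 3], explained variance [76.8 13.3  4.5]%
Spearman(assigned stage, latent stage) = 0.9986
panel 120: Lin's concordance 0.996 (almost perfect)
panel  60: Lin's concordance 0.996 (almost perfect)
panel  30: Lin's concordance 0.997 (almost perfect)
panel  12: Lin's concordance 0.995 (almost perfect)
```

Reading: screening kept all 1600 trajectory genes and dropped the 400
planted noise genes; the three stage components carry ~95 % of the
variance; the 30-step scale orders conditions in near-perfect agreement
with the generator's latent developmental stage; and shrinking the gene
set from the full core down to 12 markers barely moves the assigned
stages.

The same workflow is available from the shell:

```bash
molstage simulate --seed 5 --n-genes 400 --out sim/
molstage build-scale --expr sim/expression.tsv --meta sim/metadata.tsv --out scale.json
molstage select-panel --scale scale.json --expr sim/expression.tsv --meta sim/metadata.tsv --out-dir panels/
molstage project --scale scale.json --expr sim/expression.tsv --meta sim/metadata.tsv \
    --panel panels/panel_30.json --out proj.tsv
```

Expression files are tab-separated genes × samples tables; the metadata
TSV maps each sample column to (cultivar, vintage, timepoint, replicate,
optional doy/daf).  Scales and panels are human-diffable JSON with
full-precision numbers.

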