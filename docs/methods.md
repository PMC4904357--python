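# Methods

`parturitrack` models temporal myometrial transcriptome changes across three
mouse parturition models — spontaneous term gestation, preterm labor (PTL)
induced by progesterone-receptor blockade (RU486), and PTL induced by
intrauterine endotoxin (LPS) — and relates them to a human in-labor (IL) vs
not-in-labor (NIL) myometrium cohort. This note records the models, the
defaults and why, the numerical choices, and what the synthetic data do and
do not establish.

## Pseudotime encoding

Each model's trajectory is indexed by a pseudotime in [0, 1], the fraction of
the interval from the model's start point to labor onset:

* term gestation: E14 = 0, E16 = 0.444, E18 = 0.889, active labor (LAB) = 1
  (linear in gestational days from E14 to E18.5);
* RU486 and LPS arms: collections at 30 %, 90 %, and 100 % of the
  injection-to-labor interval, i.e. 0.3 / 0.9 / 1.0;
* vehicle controls (DMSO, PBS) carry the collection pseudotime but no
  treatment response;
* human: NIL is anchored at the mouse E18 equivalent (gestational day 263 of
  a 270-day term), encoded 0.889; IL at 1.0. Transfer correlations are
  Pearson, hence invariant to any affine recoding of these anchors.

## Synthetic data

Counts are negative binomial, `var = mu + phi * mu^2`, sampled as
gamma–Poisson. Per-gene relative abundances are log-normal (sdlog 1.2);
library sizes are log-normal (median 3e5, sdlog 0.15); per-gene dispersions
are Gamma(shape 2, rate 20), i.e. mean 0.1 — a biological CV of ~0.3, typical
of outbred animals. Expected counts are
`libsize * softmax(base_abundance * 2^(effect * pseudotime))`, so library
sizes are preserved exactly under regulation.

Gene programs (2000 genes by default) mirror the differential-expression
composition reported for this system: a small core program shared by all
three models (40 up + 60 down), a large block shared by term and RU486
(250), RU486-specific remodeling genes (250), a dominant LPS-specific
inflammatory program (500 — the inflammatory model's changes are mostly
private to it), surgery-transient genes (60) that rise after laparotomy in
both LPS-arm treatments (PBS included) and return to baseline by labor, and
840 null genes. Per-unit-pseudotime log2 effects are uniform on [1, 3] in
magnitude; core directions are fixed, other program signs random.

Two replicate-level variance components make the data realistic rather than
merely noisy:

* gestational-stage jitter — each animal's realized pseudotime scatters
  around the nominal collection time (SD 0.05), reflecting observed
  within-group stage spread;
* correlated latent factors — three per-sample factors (SD 0.15 log2) with
  standard-normal gene loadings. Independent counting noise averages out
  across the hundreds of genes a trajectory model weighs; correlated
  variation does not, and it is exactly the structured orthogonal variance
  that orthogonal signal correction exists to remove. Without it, every
  cross-model transfer correlation is ≈0.999 and the between-model contrasts
  of interest cannot manifest.

The human cohort (5 IL + 5 NIL) copies the core program fully, 70 % of the
LPS-specific program, and 20 % of the RU486-specific program into the IL
effect, over a 1:1 ortholog map covering 80 % of genes — so by construction
the human labor signature most resembles the inflammatory model. What the
synthetic data do *not* emulate: batch effects beyond the surgery transient,
gene–gene correlation within programs beyond the latent factors, length
biases, isoform structure, and outlier samples (those are planted explicitly
in QC tests). Passing tests therefore demonstrate correctness of the
machinery and qualitative reproduction of the study's structure, not
quantitative agreement with any real dataset.

## Normalization

TMM scaling factors: reference sample is the one whose 75th-percentile count
fraction is closest to the across-sample mean; per sample, M and A values of
doubly positive genes are double-trimmed (30 % on M, 5 % on A, rank-based)
and the factor is the inverse-variance-weighted mean of surviving M values,
with factors rescaled to geometric mean 1. Expression is
`log2((count + 0.5) / (libsize * factor + 1) * 1e6)`. The prior count 0.5 is
the common convention; values are finite everywhere and strictly monotone in
the count. Genes with zero counts in all samples are dropped before any
downstream step.

## Outlier QC

Within each model's sample set, genes are z-scored, samples embedded on the
top 2 principal components, and each sample's Euclidean distance to the
centroid is studentized against the leave-one-out mean and SD of the other
distances. The two-sided p-value uses a t reference with n − 2 degrees of
freedom — the standard Bonferroni outlier test. A normal reference is
markedly anti-conservative here (Monte-Carlo family-wise false-positive rate
14 % at n = 12 under ideal 2-D Gaussian scores, versus 2.7 % for the t
reference), because distances are Rayleigh-like and the leave-one-out SD
shrinks for extreme samples. Flagged samples (Bonferroni-adjusted p < 0.01)
are excluded from all downstream stages.

## Differential expression

The negative-binomial exact test operates on counts scaled to the
geometric-mean effective library size. A common dispersion maximizes the
summed conditional log-likelihood (grid search with off-grid refinement);
per-gene conditional MLEs are blended toward the common value with weight
0.7 (tagwise = 0.7·common + 0.3·per-gene). Conditional on a gene's total,
the group sums are NB with size n/phi; the two-sided p is the summed
probability of all splits at most as likely as the observed one. The
enumeration is exact (it matches an exhaustive oracle to <1e-8) and is
vectorized over genes. Benjamini–Hochberg adjustment and an FDR cutoff of
0.001 define DEG sets; the early/late-wave comparison uses 0.01.

Calibration: on homogeneous-dispersion null data with full shrinkage to the
common value, exact-test p-values on well-expressed genes (mean count
>= 50 per sample) are indistinguishable from uniform (KS); at lower counts
the exact p-values are discrete by construction and a pooled continuous
uniformity check necessarily fails.
With a Gamma spread of true dispersions, the fixed 0.7 shrinkage
under-corrects high-dispersion genes and the test is mildly liberal — a known
property of linear-shrinkage moderation; FDR at the 0.001 cutoff remains
controlled in both regimes. Full weighted-likelihood empirical-Bayes
machinery (as in mature count-model packages) is deliberately out of scope.

## OSC-PLS trajectory models

Expression of the DEG-union gene set (genes changing in ≥1 within-model
pairwise contrast) is column-standardized; pseudotime is centered and
scaled. One orthogonal-signal-correction component is estimated by a
fixed-point iteration: initialize the score t with the first principal
component, repeatedly orthogonalize t against y, set
`w_osc = X't/(t't)` (normalized), `t = X w_osc`, until the score change is
below 1e-10 (max 500 iterations). After convergence the OSC weight vector is
additionally orthogonalized against the PLS direction `X'y` and
renormalized: the training OSC score `t_osc = X w_osc` is then orthogonal to
y to machine precision while training deflation and prediction use the very
same `w_osc`/`p_osc`, so self-prediction reproduces training scores exactly.
If no variance orthogonal to y remains (degenerate input), the model falls
back to plain PLS1 with a warning. A single PLS1 component on the deflated
matrix gives weights `w = X'y/\|X'y\|` (the exported per-gene loadings),
scores `t = Xw`, and regression coefficient `q`. The weight sign is fixed so
the training score increases with pseudotime. One OSC plus one PLS component
is the default throughout; with `n_osc = 0` the procedure is plain PLS1.

Transfer: a model trained on one parturition model scores the samples of
another; the transfer correlation is Pearson r between predicted scores and
the test pseudotime, with the two-sided t-test p-value (n − 2 df). Because
each model (and species) is a separate experiment on its own time scale,
test matrices are z-scored per gene within the test cohort before
projection, both across mouse models and for the human cohort — reusing
training means/SDs across experiments amplifies genes that were flat during
training (tiny training SDs) and destabilizes the scores. Within one
experiment, prediction uses the training statistics. Vehicle-control samples
are excluded from fitting and testing; the models regress the laboring arms'
progression only.

## Clustering

Ward linkage (Ward.D2 convention) on Euclidean distances; candidate k from 2
to 10 (2 to 12 for loading matrices); the chosen k maximizes the mean
silhouette width, ties to the smallest k. Expression profiles (group means)
are row-standardized before clustering; loading matrices are clustered on
their native scale, since loadings are already comparable across models.
Identical profiles are a degenerate-input error, not a silent k = 1. Cluster
summaries divide each cluster's per-group mean by its maximum, so profiles
lie in (0, 1] for nonnegative expression input.

## Cross-species comparison

Human IL-vs-NIL DEGs (same exact test, FDR < 0.001) are mapped through the
1:1 ortholog table and intersected with the mouse DEG union; mouse models
are refit on this shared gene set (the models must share features with the
human matrix; refitting is the only coherent choice) and the human samples
scored as above. The per-gene loadings of the three refit models form the
matrix clustered for cross-species profile groups.

## Enrichment stand-ins

Over-representation uses the hypergeometric upper tail (one-sided Fisher)
within a user-supplied universe; sets are flagged at −log10 p > 1.3. The
signed activation score is `z = (consistent − inconsistent)/sqrt(overlap)`
against an expected-sign edge list, with |z| ≥ 2 called
activated/inhibited. No pathway content is bundled; commercial knowledge
bases are proprietary and out of scope.

## Problem sizes and determinism

Default study conditions: 2000 genes, 4 replicates per group (48 mouse
samples), 5+5 human samples. The replicate studies in the tests and in
`scripts/acceptance.py` use 20 pipeline replicates for the transfer
statistics, 50 null datasets for calibration, 50–100 planted datasets for QC
and cluster recovery; one full pipeline replicate takes a few seconds. Every
stochastic step draws from a generator seeded from the user-supplied seed
(the human cohort uses an independent stream derived from the same seed), so
identical configuration and seed give byte-identical outputs.

## Known limitations

* Effects are linear in pseudotime on the log2 scale; a late acceleration
  near labor is not modeled, so contrasts between adjacent late time points
  (E18 vs LAB) recover few genes and the "late wave" is small in synthetic
  data.
* The exact-test dispersion machinery is a deliberate simplification of
  full quantile-adjusted conditional ML with weighted-likelihood shrinkage;
  DEG counts on real data will differ from reference implementations in
  detail, though the test structure is identical.
* The human cohort shares the mouse's abundance spectrum and dispersion
  prior; real cross-species comparisons face annotation and platform
  differences the ortholog table abstracts away.
* Transfer correlations on synthetic data sit higher than on real cohorts;
  the qualitative ordering (term ↔ RU486 strong, LPS-trained weakest, human
  best matched by LPS) is the reproducible object, not the r values.
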