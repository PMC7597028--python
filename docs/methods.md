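# Methods

`oritrace` implements a cell-of-origin tracing analysis for high-grade
serous ovarian cancer (HGSOC). The premise is that tumors retain part of the
DNA methylation print of their tissue of origin, so a signature of CpGs that
separates the two candidate origins — fimbrial epithelium (FI) and ovarian
surface epithelium (OSE) — can be read out in tumors even though most
genome-wide methylation variance is driven by tumor-vs-normal differences.
This note records the models, the parameters that matter, the numerical
choices, and what the synthetic cohort does and does not emulate.

## Data model and conventions

Methylation is carried as paired beta (methylation fraction, in (0,1)) and
M (log2-odds, `M = log2(beta/(1-beta))`) matrices, CpGs as rows. Differential
testing is done on M values, whose variance is approximately independent of
the mean; clustering, embeddings and pseudotime use beta values. Both
defaults are switchable. Beta values are clipped to
`[1e-6, 1-1e-6]` before the logit so M stays finite.

Batch adjustment is a deterministic two-moment stand-in for empirical-Bayes
correction: per feature, group x batch cell means are computed, each sample
is re-centered on its group's cross-batch mean (removing additive batch
offsets and batch x group interactions), and cell-centered residuals are
rescaled to the pooled within-batch scale. The construction is exactly
idempotent and protects the biological grouping by design. A matrix
corrected by a full empirical-Bayes implementation can be supplied instead;
the downstream stages only see the matrix.

## OriPrint signature

Origin-differential CpGs are called with a moderated two-group t-statistic
on M values: per-CpG pooled variances are shrunk toward a common prior,
`s2_post = (d0*s0^2 + d*s2)/(d0 + d)`, with the prior degrees of freedom
`d0` and scale `s0^2` estimated by matching the mean and variance of
`log(s2)` across CpGs to a scaled-F model (the trigamma inverse is solved by
Newton iteration). `t = delta_M / (s_post * sqrt(1/n1 + 1/n2))` is referred
to a t distribution on `d0 + d` degrees of freedom; with `d0 = 0` the
statistic reduces exactly to the ordinary pooled t-test, which the test
suite uses as an oracle. P-values are Benjamini-Hochberg adjusted.

The signature keeps CpGs with adjusted p < 0.05 and |delta-M| > 1 (both
configurable), split into hyper- and hypomethylated-in-OSE sets. The
threshold on |delta-M| is read two-sided, consistent with a signature that
contains both directions. Prior-trend and robust variants of the shrinkage
are not implemented (off by default in the reference tooling as well).

## Origin classification

Tumors are classified in "OriPrint space" — beta values restricted to the
signature CpGs — by three transductive clustering routes:

* **Pearson/Ward**: agglomerative clustering with the Ward update on a
  precomputed `1 - r` correlation-distance matrix (the `ward.D2`
  convention), cut at two clusters.
* **Louvain**: modularity communities on a symmetrized unweighted kNN graph
  (k = 20) over the top 50 principal components (capped at n-1), merged by
  nearest-centroid agglomeration until exactly two remain. Seeded.
* **Density**: HDBSCAN on diffusion-map coordinates, reduced to exactly two
  clusters by nearest-centroid merging, noise points assigned to the nearer
  surviving centroid.

Cluster sides are named by **normal anchoring**: the cluster holding more FI
than OSE normals is FI-like and conversely; clusters without normals (or
with ties) fall back to Pearson correlation of the cluster centroid against
the FI and OSE normal centroids. The two clusters always receive different
sides.

A two-component full-covariance Gaussian mixture serves as an independent
check. It is fit on the tumors' coordinates in the first two principal
components (best log-likelihood of 2000 seeded random restarts, initialized
from random data points — random-responsibility initialization tends to
collapse both components onto the centroid); normals are assigned by
posterior argmax and used only for naming.

Per-tumor votes are fused by a consensus rule: consistency is the largest
label share among methods, the consensus is the majority label when
consistency reaches 0.75 and "uncertain" otherwise. With three methods a
2-of-3 majority (consistency 0.667) is therefore uncertain; a threshold of
0.66 reproduces strict-majority behavior. Overall concordance is the
fraction of tumors on which all methods agree.

## Diffusion maps and dual-rooted pseudotime

The diffusion map uses a symmetrized kNN neighborhood (k = 20), a Gaussian
kernel with per-point adaptive bandwidth (distance to the k-th neighbor),
anisotropic density normalization (alpha = 1) and the row-normalized
transition operator; eigenpairs come from the symmetric conjugate.
Components are the nontrivial right eigenvectors scaled by their
eigenvalues; the default keeps 15 components. Diffusion pseudotime from a
root is the Euclidean distance between accumulated-transition
representations `sum_i (lambda_i/(1-lambda_i)) psi_i`; eigenvalues are
clipped away from 1 by 1e-10 to keep the accumulation finite on
near-disconnected graphs.

Roots are selected automatically as the most peripheral sample of each
normal class (maximal |component 1|, ties broken by sample id). The
published analysis chose roots visually; extremity on the leading component
is the deterministic equivalent. The two time lines are intersected at the
sample minimizing |scaled FI pseudotime - scaled OSE pseudotime| (ties: first
sample id, with a degeneracy flag when the two pseudotimes are identical),
and **tumor intermediacy** is the fraction of tumors whose FI-rooted
pseudotime rank lies strictly between the median ranks of FI and OSE
normals. "Tumors are a mandatory step between the origins" is
operationalized as: the intersection sample is a tumor, and intermediacy is
high in OriPrint space but not in the full-CpG space.

## Transcriptomic translation

Counts are normalized by trimmed-mean-of-M-values (TMM): reference library
closest to the mean 75th-percentile count fraction; gene-wise log-ratios
doubly trimmed (30% per tail on M, 5% per tail on absolute intensity) and
averaged with inverse-asymptotic-variance weights; factors rescaled to
geometric mean 1. logCPM uses effective library sizes with a
library-size-scaled prior count of 0.5, which makes exactly proportional
libraries identical after normalization (an unscaled prior would not).

Differential expression reuses the moderated test on logCPM with FDR < 0.05
and |logFC| > 0.8. The coherent signature is the intersection of genes
significant and same-signed in two evidence sets (cultured cells and FFPE in
the published design). External cohorts are stratified on the signature by
z-scoring per gene, scanning Louvain resolutions over [0.1, 1.5] (15 grid
points) and keeping the partition most stable under the scan (maximal mean
adjusted Rand index with its grid neighbors, among partitions with at least
two communities); the two communities with the most distant centroids in
diffusion coordinates are retained and all other samples are uncertain. For
the diffusion embedding the neighborhood size is grown until the kNN graph
is connected, because a k suited to community detection can leave
well-separated clusters as disconnected components with rotation-arbitrary
eigenvectors. Retained clusters are named by the signed concordance score
(mean over signature genes of sign(cluster mean z) x direction); the higher
score is OSE-like.

The robustness filter trains a bagged ensemble of decision trees on random
patches (80% sample x 80% feature subsets per tree) of a stratified 70/30
train split, and repeats this over re-drawn gene subsets (half of the genes
per iteration) and re-drawn splits; both perturbations are re-drawn every
iteration so a sample's held-out predictions span many splits and many gene
subsets, and the two iteration counts simply budget the total. The ensemble
is grown by doubling (16 -> 64 trees by default) until test predictions
change by less than 1% between doublings. A sample's consistency is the
fraction of its held-out appearances predicted with its modal label;
samples below 75% are uncertain. Package defaults run 100+100 iterations;
the published 1000+1000 scale is a configuration change. The model is fed
the differential genes, matching the published procedure.

## Survival

Kaplan-Meier curves use the product-limit estimator; medians are the
smallest time with S(t) <= 0.5 and are flagged undefined when the curve
never reaches 0.5. The log-rank test accumulates observed-minus-expected
events with the exact hypergeometric variance at tied event times and
refers U^2/V to chi-square on 1 df. Cox proportional hazards delegates to
lifelines (Breslow ties), with a quantile-threshold helper for continuous
covariates. Analyses restrict follow-up to a 5-year horizon (1826 days;
times beyond are censored at the horizon) by default, and uncertain samples
are excluded from two-group contrasts.

## Synthetic cohort

The generator produces the statistical structure the analysis assumes, with
a truth channel for recovery tests. Defaults (the study conditions for all
seeded tests): 12 FI, 8 OSE, 24 tumors; 20,000 CpGs with 1,000 planted
origin-differential CpGs at |delta-M| = 2.5; tumors inherit their origin's
state per planted CpG with probability 0.9; a single shared aberration
field (SD 1.5 M units over 30% of the non-planted CpGs) plus i.i.d. noise
(SD 0.5) gives all tumors a common displacement that dominates global
variance — the variance hierarchy in which normals-vs-tumors leads
genome-wide while the origin signal leads in the signature subspace. The
shared field excludes the planted CpGs so that at fidelity 1 and vanishing
noise a tumor's signature restriction equals its origin's pattern exactly.
Baseline CpG states are a symmetric two-mode mixture at M = +/-3 (SD 1), so
beta values are bimodal as on arrays.

Expression is negative binomial (dispersion 0.15) with 150 planted
origin-differential genes at log2FC 2 split symmetrically between origins,
gene base abundances log-uniform over ~2^3..2^9, and library sizes
log-uniform over a 4-fold range. Survival is exponential with FI median
1460 days and an OSE:FI hazard ratio of 2 (the direction and rough scale of
the published subtype contrast), independent censoring with probability
0.15 (censoring time uniform over the unobserved event time), and
administrative censoring at a 10-year simulated follow-up; the 5-year
restriction is applied at analysis time. The pipeline simulates its
retrospective expression/survival cohort with 150 patients, the size of a
typical clinical FFPE series, rather than reusing the 24 methylation
tumors, whose log-rank power would be negligible.

What the generator does **not** emulate: array probe chemistry and probe-
type effects, genomic autocorrelation of methylation, copy-number-driven
intensity artifacts, tumor purity gradients, per-tumor private aberration
fields, overdispersion heterogeneity across genes, or informative
censoring. Passing tests therefore certify the pipeline's statistical
machinery under the assumed generative structure, not its behavior on any
real cohort.

## Problem sizes and determinism

Every stochastic component draws from per-stage child streams of one seed,
so reruns are byte-identical and changing one stage's internals cannot
perturb another's draws. Seeded test and pipeline runs use the default
cohort sizes above; replicated checks use 20-500 replicates (20 seeds for
trajectory properties, 100 for survival power, 500 for closed-form median
recovery), chosen so Monte-Carlo error is small against the margins being
asserted.

## Known limitations

* The bagging consistency score depends on the stability of a sample's
  neighborhood, so label-shuffled data can still yield confidently (and
  wrongly) classified samples; the uncertain fraction under shuffling is a
  majority but not near 1.
* The density route requires at least two density clusters; cohorts whose
  signature space is unimodal fail loudly rather than guessing.
* The moderated test on logCPM is a normal-theory stand-in for count-based
  differential expression; at very low counts a negative-binomial model
  would be more faithful.
* Cox PH inherits lifelines' behavior under separation (flagged by its own
  warnings) rather than implementing a custom penalization.
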