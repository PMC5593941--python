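# Methods

This note records the statistical model behind `metadeg`, the defaults and
why they were chosen, and what the synthetic benchmark does and does not
demonstrate.

## Differential score

For a transition `from_group → to_group`, gene *i* receives

D\_i = log2(FC\_i) · (−log10 P\_i)

* **log2(FC)** is the difference of per-group means of the log2-scale
  matrix (inputs are assumed already log2; a `--log2` CLI flag applies
  log2(x+1) to raw values). Computing the fold change as a difference of
  log means rather than a log of a ratio of raw means keeps it linear in
  the data the pipeline actually consumes.
* **P** is the two-sided Wilcoxon p-value: signed-rank across complete
  pairs when the design is paired, rank-sum otherwise. The exact null
  distribution is used whenever the total observation count allows
  enumeration (≤ 25) and the gene has no ties; otherwise the normal
  approximation with tie and continuity correction. Two-sided p-values
  were chosen so that the sign of D is carried entirely by the fold
  change; a one-sided p would double-count direction.
* P is floored at 1e-300 purely as numeric safety — far below any p
  attainable at realistic cohort sizes — so D can never be infinite.
* Genes with every value tied get p = 1 and a `degenerate` flag rather
  than an error: they are real occurrences in filtered public matrices.

A classical baseline (`t_test_deg`: paired or pooled-variance Student t
with Benjamini–Hochberg FDR) is provided because at small between-stage
effect sizes it typically calls nothing, which is the motivation for the
score in the first place.

## Significance calling

The score vector is summarised by its sample mean and SD (n−1). Calls are
one-sided: a gene at or above the mean is assessed in the upper tail,
below it in the lower tail, significant iff tail\_p < α strictly
(default α = 0.05). The one-sample Kolmogorov–Smirnov statistic of the
scores against the fitted normal is computed (asymptotic p, no Lilliefors
correction) and *reported only* — calling is not gated on it. The null
score distribution is in fact strongly leptokurtic (D behaves like
c·z·|z| in the tails), so the fitted-normal tails flag roughly 7–8%
rather than the nominal 10% of null genes at α = 0.05 across both tails;
the KS statistic in the output is the caveat the user should read.
Moments rather than a robust fit are used deliberately: with planted (or
real) DEGs present, the inflated SD makes the procedure conservative in a
transparent way.

`select_top_n` orders by score (descending for up, ascending for down)
and breaks score ties by lexicographic gene id so repeated runs return
identical lists.

## Cox screening and AACCV

Every gene is z-scored (so coefficients are log-hazards per expression SD
and their absolute values are comparable across genes) and fitted in its
own univariate Cox proportional-hazards model over all cancer samples
with survival data. The solver is an in-package Newton iteration on the
Breslow partial likelihood, vectorised across genes; standard errors come
from the observed information and p-values are two-sided Wald. Breslow tie
handling is the simplest choice and matches the solver's closed-form
suffix-sum structure. Fits that do not converge (|step| ≥ 1e-9 after 50
iterations, or |β| > 50, which indicates separation) are flagged and
excluded from averages rather than clipped — one diverging coefficient
would otherwise dominate an average meaninglessly. Constant genes are
flagged degenerate with β = 0.

The AACCV of a transition at list size N is the mean |β| over its top-N
genes by differential score; curves over N ∈ {2000, 1500, 1000, 500} (or
scaled-down lists on synthetic data) are compared between transitions
with a two-sided rank-sum test on the member |β| lists, concatenating the
up and down lists for bi-directional comparisons. The multivariate /
stepwise Cox fits in the prognosis stage use lifelines, whose tie rule is
Efron; on continuous synthetic survival times ties have probability zero
and the two rules coincide.

## Network module

Edge lists (two-column TSV, or SIF with fan-out lines) are read as
undirected simple graphs: self-loops and duplicate or reversed edges are
dropped with logged counts, node identity is exact case-sensitive string
match (identifier harmonisation is data curation, out of scope), and any
direction annotation is discarded. Merging is the plain union of nodes
and edges. The module of a DEG set is the largest connected component of
the induced subgraph; ties between equal-sized components break toward
the one containing the lexicographically smallest gene so extraction is
deterministic.

## Prognostic validation

PC1 of the gene-centred module submatrix summarises the module per
sample; its sign is fixed so the sum of gene loadings is nonnegative
(otherwise the SVD sign ambiguity would flip hazard-ratio directions
between runs and platforms). Samples above the median PC1 form the
"high" arm; exact-median samples go to "low", giving arms differing by at
most one for distinct scores. The arms are compared with Kaplan–Meier
curves and the two-group log-rank test (lifelines).

"Stepwise" Cox is implemented as a univariate screen of each factor (age
continuous; sex as male-vs-female; stage as later-stage-vs-lowest; the
module as the binary PC1 group, with continuous PC1 available as an
option) at p < `alpha_enter` (default 0.05), followed by **one** joint
multivariate fit of the survivors — no iterative add/drop. Samples
missing any factor are removed listwise. Factors failing the screen are
returned with an `excluded` marker; constant factors are `degenerate` and
never enter.

## Preprocessing

* **Missing-gene filter**: a gene is dropped iff its missing count
  strictly exceeds half the size of at least one subgroup (subgroups =
  the four stage labels). Strict "more than half" means a gene missing in
  exactly half of every subgroup survives.
* **k-NN imputation** (default k = 10, the customary default of the
  reference implementations of this scheme): a missing entry (g, s) is
  the mean over the k genes nearest to g — by root-mean-square difference
  over commonly observed samples — of their values in s. The RMS
  (per-entry normalised) form was chosen over a raw Euclidean sum so that
  candidate genes with many shared observations are not penalised for
  them. Ties break by gene order; a gene with no eligible neighbour in a
  sample falls back to its own mean with a logged warning.
* **Cyclic loess** (span 0.7, 3 iterations, degree-1 lowess with 3
  robustness iterations): for every unordered sample pair in lexicographic
  column order, the loess trend of M on A is split half-and-half between
  the two samples. Imputation precedes normalisation because the loess
  fits need complete pairs. The smoother is evaluated on an interpolation
  grid (delta = 5% of the A-range), which changes fitted values well
  below the between-pass convergence tolerance while making full passes
  over all C(n,2) pairs affordable.

## Synthetic cohorts

The generator emulates the study conditions the pipeline assumes, on the
scale of a desk-size cohort:

* Expression is gene-wise Gaussian **on the log2 scale**:
  baseline (8.0) + planted group shift (±1.0 log2 units for 60 up / 60
  down genes in the later group of the configured transition, default
  confined → lymphnode) + a shared subject effect (SD 0.5) linking each
  normal sample to its paired confined tumour + N(0, 1) noise; 1% of
  entries are then masked as missing. Simulating post-normalisation
  values directly isolates the statistics under test from quantification
  noise models.
* Default cohort: 15 paired normals, 30 confined, 22 lymphnode, 10
  metastasis — reproducing the strong confined > lymphnode > metastasis
  imbalance of staged cohorts at roughly one-quarter scale, with 1200
  genes so a full pipeline run (including all-pairs cyclic loess) takes
  tens of seconds.
* Survival is exponential proportional hazards: log-hazard =
  `surv_beta` (default 0.5) × standardised PC1 of the signature genes
  (default: the planted module), baseline hazard 1/1000 per day (median
  survival ≈ 1.9 years for an average patient, a realistic
  adenocarcinoma scale). Censoring is independent uniform on (0, c\_max)
  with c\_max solved numerically so the expected censored fraction equals
  `censor_rate` (default 0.4) — the simplest mechanism satisfying the
  independent-censoring assumption of the Cox model.
* The network is a uniform random simple graph (400 nodes, 1600 edges by
  default) whose nodes are gene ids; the planted 20-gene module is wired
  as a random spanning tree plus whatever uniform edges land inside it,
  and edges between planted DEGs outside the module are excluded, so the
  module is exactly the biggest connected component of the planted DEG
  projection by construction.
* All randomness flows from one master seed through three independent
  streams (expression / survival / network), so enlarging the gene panel
  never perturbs the survival draws.

**What passing the synthetic benchmark does not show.** The generator has
no count noise, no library-size or batch structure, no platform effects,
no correlated co-expression modules beyond the planted signature, and
independent censoring; recovery rates measured on it are upper bounds on
what identically-tuned analyses achieve on real RNA-seq or microarray
cohorts, and the network model says nothing about the degree
heterogeneity of curated interactomes.

## Numerical choices and degenerate inputs

* Newton steps in the Cox solver are clipped to ±2 per iteration and the
  per-gene weights are rescaled by their row maximum before
  exponentiation (the rescaling cancels in every likelihood ratio), so
  separation cannot overflow.
* PCA everywhere uses SVD of the gene-centred matrix with the
  nonnegative-loading-sum sign rule; a brute-force eigendecomposition
  oracle checks it in the tests.
* Degenerate cases are first-class: all-tied genes (p = 1, flagged),
  constant Cox covariates (β = 0, flagged), zero-variance score vectors
  (error — a normal fit is undefined), empty DEG∩network intersections
  (empty module plus warning), exact-median PC1 scores (assigned low).

## Problem sizes in the shipped checks

The test-suite and the acceptance script run entirely on generated data:
10,000 genes for the null calling rate, 1,000 genes × 50 planted for
recall, 100 random networks (≤ 200 nodes) against a union-find oracle,
100 seeds for module recovery, 1,000 log-rank and 200 stepwise-Cox
replicates for calibration and coverage, 100 replicates of the 6,000-gene
AACCV comparison, and two full pipeline runs for byte-identical
manifests. These sizes keep the whole suite within a few minutes on one
CPU while leaving binomial noise well inside the asserted bands.

## Known limitations

* The score's null distribution is not normal; the fitted-normal tails
  are a calling convention, not calibrated p-values (the KS statistic is
  reported precisely so users see this).
* `cox_per_gene` fits marginal models; correlated genes share credit.
* The stepwise table inherits the usual caveats of screen-then-fit
  inference; its p-values are not selection-adjusted.
* No multiple-testing correction is applied to the tail calls, matching
  the method being reproduced.
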