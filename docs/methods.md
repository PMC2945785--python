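# Methods

## Overview

`rnadiff` computes gene-level differential expression from aligned
RNA-seq reads in five stages: gene interval models from an exon
annotation, anchor-based read counting, per-sample normalization
factors, per-gene generalized-linear-model (GLM) tests, and
experiment-level summaries. A synthetic-data generator drives the
type-I-error calibration experiment that motivates the statistical
design: with biological replicates, gene counts are overdispersed
relative to the Poisson, and a Poisson test under the global null
rejects far more often than its nominal level.

## Gene interval models

Every gene's exon annotation is reduced to one set of disjoint genomic
intervals:

* **union-intersection** (default): the bases contained in *every*
  transcript annotated for the gene — its constitutive portion. Counts
  over these bases are comparable across samples regardless of isoform
  usage.
* **union**: the bases contained in *any* exon of the gene.

After per-gene construction, any base claimed by two or more genes is
removed from all genes, so the final sets are pairwise disjoint and a
read maps to at most one gene. Genes reduced to zero length are kept in
the gene table (they collect zero counts and are removed by the
expression filter); this keeps the gene universe traceable.

Coordinates are 0-based half-open internally. GTF/GFF3 input (1-based
closed) is converted on read; BED6 is the export format and is written
natively. Adjacent intervals are merged so that equal base sets have
equal representations. Genes whose transcripts span multiple
chromosomes or strands occur in real annotations; they are skipped with
a logged warning rather than failing the run. Single-transcript genes
need no special case: the intersection over one exon set is itself.

All interval arithmetic is tested against a brute-force per-base bitmap
oracle on random toy annotations; the interval route must agree
exactly.

## Anchor counting

Each retained alignment is represented by its aligned reference span
(soft-clipped bases excluded) and reduced to an anchor:

* **3'-most base** (default): the highest reference coordinate of the
  span on the plus strand, the lowest on the minus strand (the
  biological 3' end of a minus-strand read sits at the lower
  coordinate).
* **5'-most k bases**: the first k bases from the 5' end; the read is
  assigned if *any* of them falls in a gene set (the all-bases
  alternative is not implemented).

Because gene sets are disjoint, each alignment produces zero or one
overlap record, so total assigned counts never exceed retained
alignments and counting is independent of input order and of how the
stream is partitioned across workers. Membership lookup is a binary
search over sorted interval starts, oracle-checked per-base in tests.

Reads flagged as multi-mapped (NH tag > 1) are dropped; absent such
metadata the input is trusted as pre-filtered to unique alignments,
since uniqueness is the aligner's knowledge, not recoverable
downstream. Unmapped records are skipped and tallied.

## Normalization

Genes with zero counts in every sample are removed first; a single read
anywhere retains a gene. Per sample, the factor q_j is:

* **quantile p of non-zero counts** (default p = 0.75, upper-quartile
  normalization). Zeros are excluded before taking the quantile. The
  quantile estimator interpolates linearly between order statistics
  (the convention of most statistical software); a nearest-rank
  alternative is available behind a flag since the estimator choice is
  a genuine convention, not a derivable fact.
* **median**: quantile 0.5 of non-zero counts.
* **total**: the column sum, zeros included.

Factors are computed on the post-filter matrix. Computing them on the
full annotated universe instead would only add zeros, which the
quantile methods ignore; the choice matters only for `total`.

## Statistical model

For gene i with counts c_ij and outcome y_j the model is

    g(E[f(c_ij) | y_j]) = b_i0 + eta_i · log(q_j) + Σ_k b_ik s_k(y_j)

* Poisson family: g = log, f = identity.
* Gaussian family: g = identity, f(c) = log(c + pseudocount). The
  pseudocount defaults to 0.5 — zeros occur per-sample even after the
  expression filter — and is configurable.
* Normalization as **offset**: log(q_j) enters the linear predictor
  with eta_i fixed at 1. As **term**: eta_i is estimated per gene, a
  nuisance present under both hypotheses. If log(q_j) is constant
  across samples the term is dropped with a warning (it would be
  collinear with the intercept).
* Outcome: a K-group factor encoded as reference-level dummies (K − 1
  test columns) or a continuous covariate (one column, s = identity).
  A K-group factor plus an intercept with all K coefficients free is
  not identifiable, so the test has df = K − 1 — the identifiable
  contrast of the same null hypothesis.

The test statistic is D_i = 2(loglik_full − loglik_null), clamped at 0
against fit noise. Asymptotic p-values are the upper chi-square tail
with df degrees of freedom, floored at 1e−300 so p stays in (0, 1].

Poisson models are fit by iteratively reweighted least squares,
vectorized across genes (per-gene weighted normal equations solved as a
batched linear system); convergence is a relative deviance change below
1e−8, with a 50-iteration cap. Non-converged genes are flagged but
still reported from the best iterate. Perfectly separated genes (e.g. a
group with all-zero counts) have divergent coefficients but convergent
deviance, handled by the 0·log 0 := 0 convention and a linear-predictor
clip at ±30. Gaussian models are least squares with the profile
log-likelihood, so D_i = n·log(RSS_null/RSS_full); if both residual
sums vanish (all transformed counts identical) D is defined as 0. The
Gaussian two-group D is a monotone function of the squared pooled
t-statistic; a literal regression t-test (finite-sample exact under
normality) is exposed via `gaussian_test="ttest"` for single-contrast
designs, with the LRT as the default.

Per-gene computations are independent; the pipeline chunks genes across
a thread pool and concatenates in gene order, so outputs are bitwise
identical for any worker count.

## Permutation inference

The outcome labels are permuted B times globally — the same permutation
applied to all genes in a given round, preserving cross-gene structure —
and the identical fitting procedure produces an m × B null matrix. The
pooled permutation p-value is

    p_i = (#{D_j^0b > D_i over all j, b} + 1) / (m·B + 1)

with strict inequality (ties do not exceed), computed by sorting the
pooled nulls once and scanning the observed statistics against them;
tests verify exact agreement with quadratic brute-force counting.
Pooling across genes assumes the null statistics are exchangeable
across genes, which trades gene-specific resolution for a much finer
p-value grid at small B. The permutation generator is seeded and the
seed recorded.

## Summaries

Q-values are Benjamini-Hochberg step-up adjustments
(q_(i) = min_{j≥i} m·p_(j)/j, capped at 1), optionally multiplied by a
π0 estimate supplied by the caller; BH with π0 = 1 is the conservative,
fully specified default and no particular π0 estimator is claimed.
RPKM_ij = c_ij / ((L_i/10³)(N_j/10⁶)) with L_i the gene model length
and N_j defaulting to the sample's assigned-read total (computable
self-contained); an externally supplied total — e.g. all uniquely
aligned reads — can replace it. Zero-length genes get NA. Top-N
ranking sorts by p ascending with gene_id as tie-break and includes
every gene tied at the Nth p-value, so the cut is deterministic without
arbitrary truncation; overlap records are then filtered to the top
genes.

## Synthetic data

Counts are drawn with mean d_j·λ_i·fold, where:

* d_j — depth multipliers, log-uniform on [0.5, 2] by default: enough
  spread to exercise normalization without dominating it;
* λ_i — baseline expression, log-normal with meanlog = log 100,
  sdlog = 1 (median gene mean 100 counts, bulk genes spanning roughly
  1–10⁴ at desk scale);
* fold — applied to planted DE genes in the second group (fraction and
  fold configurable; 0 and 1 by default, the global null);
* replication — Poisson draws (technical), or Gamma-Poisson with
  Var = μ + φμ² (biological; the standard negative-binomial
  overdispersion parameterization). φ = 0.5 is the overdispersed
  condition used in the calibration runs.

All randomness flows from a single recorded seed. The read simulator
places each read so its 3'-anchor base is uniform over the gene's
interval set, with random strand and per-sample read groups, emitting
valid SAM — so an overlap-count round trip must recover the planted
counts exactly. The generator does *not* model sequencing error,
junction reads, GC/length bias, or realistic base qualities; passing
calibration here shows the statistical engine behaves as designed under
its own model assumptions, not that any particular real dataset is
Poisson or Gamma-Poisson.

## Calibration experiment

Samples are randomly assigned to two groups with no planted signal, so
p-values should be uniform and a fraction α of genes significant at
level α (for 14,934 genes at the 5% level, 747 genes). Six strategies
are compared: {Poisson LRT, Gaussian LRT, Gaussian statistic with
permutation p-values} × {normalization as offset, as term}. The default
problem size is m = 2,000 genes, n = 20 samples (10 per group), B = 20
permutations — sizes at which each full six-strategy run takes well
under a minute on one CPU while leaving the binomial sampling band
around α narrow enough to detect miscalibration. Under matched Poisson
data the Poisson test sits inside the 99% binomial band around 5%;
under φ = 0.5 its rejection fraction rises above 70%, while the
Gaussian and permutation strategies stay near nominal — the ordering
the method exists to demonstrate.

## Pipeline determinism

A run manifest (flat key=value text) records every parameter and
per-stage record counts; outputs are pure functions of the manifest.
Floats are written with a fixed `%.10g` format so reruns — whole, staged,
or with different thread counts — are byte-identical. Exit codes:
0 success, 2 configuration error, 3 stage failure.

## Known limitations

* No junction/spliced-read handling; reads across exon boundaries can
  only anchor by their terminal base's position.
* No fractional assignment of multi-mapped reads and no paired-end
  fragment logic.
* The trimmed-mean test statistic and variance-moderated
  (empirical-Bayes) tests are out of scope.
* Asymptotic chi-square p-values degrade for very low-count genes;
  the permutation route is the remedy the package offers.
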