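# rnadiff

Gene-level differential expression for RNA-seq, built around
constitutive gene interval models, 3'-anchor read counting,
upper-quartile normalization, and generalized-linear-model tests with
asymptotic or pooled-permutation inference — plus a synthetic-data
generator for calibrating the tests' type-I error under technical
(Poisson) versus biological (overdispersed) replication.

It is for analysts who have aligned, uniquely-mapped reads (SAM/BAM)
and an exon annotation (GTF/GFF3) and want per-gene p-values, q-values,
and RPKM tables — and for anyone who wants to see, on data they can
regenerate, why a Poisson test on biological replicates vastly
overstates differential expression.

## The model

Each gene is reduced to its constitutive interval set (bases covered by
*every* annotated transcript, with bases shared between genes removed
from all genes), and a read is counted for a gene when its 3'-most
aligned base falls in the gene's set, giving counts c_ij for gene i and
sample j. With q_j the 75th percentile of sample j's non-zero gene
counts, the test fits

    g(E[f(c_ij) | y_j]) = b_i0 + η_i log(q_j) + Σ_k b_ik s_k(y_j)

(Poisson: g = log, f = identity; Gaussian: g = identity,
f = log(c + ½); η_i ≡ 1 when normalization is an offset, estimated when
it is a model term) and reports the likelihood-ratio statistic
D_i = 2(ℓ_full − ℓ_null) with a χ²(K−1) tail p-value, or a pooled
permutation p-value

    p_i = (#{D_j^0b > D_i} + 1) / (mB + 1)

over B global label permutations of all m genes.

## Worked example

Simulate a small experiment and run the whole pipeline:

```
$ rnadiff sim --genes 6 --samples 4 --seed 3 --out-prefix clitest
$ rnadiff run --annotation clitest.gtf --sample-sheet clitest.samples.tsv \
      --out cliout --family gaussian -B 3 -N 2
$ head -3 cliout/stats.tsv
gene_id	D	df	p_asymptotic	p_permutation	converged
G001	1.825803151	1	0.1766240617	0.4210526316	True
G002	0.6668995104	1	0.4141346718	0.5263157895	True
```

`D` is the likelihood-ratio statistic for a group difference in each
gene's (log-transformed, normalized) counts, `p_asymptotic` its
chi-square tail with 1 degree of freedom, and `p_permutation` the
pooled exceedance p-value over 3 label permutations × 6 genes (its
floor is 1/19 ≈ 0.0526 here, which is why tiny B is only a smoke test).
The output directory also holds the interval BED, raw/filtered count
tables, normalization factors, sorted p- and q-value tables, an RPKM
table and the top-gene overlap dump; `manifest.txt` records every
parameter, and reruns are byte-identical for any `--threads`.

The calibration experiment shows the headline contrast. Under the
global null with Gamma-Poisson (biological) replication, φ = 0.5,
m = 2,000 genes, n = 20 samples:

```
$ rnadiff calibrate -m 2000 -n 20 --dispersion 0.5 -B 20 --seed 2010
family	norm_mode	inference	alpha	m	n_significant	fraction_significant	expected_significant
poisson	offset	asymptotic	0.05	2000	1546	0.773	100
poisson	term	asymptotic	0.05	2000	1571	0.7855	100
gaussian	offset	asymptotic	0.05	2000	154	0.077	100
gaussian	term	asymptotic	0.05	2000	161	0.0805	100
gaussian	offset	permutation	0.05	2000	125	0.0625	100
gaussian	term	permutation	0.05	2000	120	0.06	100
```
(rows at α = 0.01 omitted)

A nominal-5% Poisson test rejects 77% of null genes once counts are
biologically overdispersed, while the Gaussian and permutation
strategies stay near 5%; with `--dispersion 0` (technical, Poisson
replication) the Poisson test is itself well calibrated (fraction
0.0505 with this seed).

The same machinery is a library:

```python
from rnadiff import SimulationConfig, null_calibration_experiment
report = null_calibration_experiment(SimulationConfig(dispersion=0.5))
print(report.table)
```

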