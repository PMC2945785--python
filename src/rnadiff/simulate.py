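"""Synthetic annotations, alignments and count matrices.

The generator emulates the statistical structure of a population
RNA-seq experiment at desk scale: genes with log-normal baseline
expression, sample-specific sequencing depths, and replicate count
variation that is Poisson (technical replication, variance = mean) or
Gamma-Poisson / negative binomial (biological replication, variance =
mu + phi * mu^2). It backs the null-calibration experiment: samples are
randomly split into two groups with no planted signal, the six testing
strategies (Poisson / Gaussian / permutation x normalization as offset /
as term) are run, and the fraction of p-values below alpha is compared
with the nominal level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence, TextIO

import numpy as np
import pandas as pd
import pysam

from . import de_stats, normalize
from .gene_models import GeneIntervalSet
from .overlap_counter import CountMatrix

__all__ = [
    "SimulationConfig",
    "STRATEGIES",
    "CalibrationReport",
    "simulate_counts",
    "simulate_annotation",
    "simulate_alignments",
    "null_calibration_experiment",
    "expected_significant",
]

#: The six testing strategies of the randomized-label experiment:
#: (family, normalization mode, inference). The permutation strategies
#: use the Gaussian statistic with pooled permutation p-values.
STRATEGIES: tuple[tuple[str, str, str], ...] = (
    ("poisson", "offset", "asymptotic"),
    ("poisson", "term", "asymptotic"),
    ("gaussian", "offset", "asymptotic"),
    ("gaussian", "term", "asymptotic"),
    ("gaussian", "offset", "permutation"),
    ("gaussian", "term", "permutation"),
)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic experiment.

    Counts for gene i in sample j are drawn with mean
    d_j * lambda_i * fold^(gene is DE and j in group 2), where d_j is a
    log-uniform depth multiplier and lambda_i a log-normal baseline
    (median exp(baseline_meanlog) counts at depth 1). ``dispersion`` is
    phi in Var = mu + phi mu^2; phi = 0 gives pure Poisson draws.
    """

    m_genes: int = 2000
    n_samples: int = 20
    n_groups: int = 2
    depth_range: tuple[float, float] = (0.5, 2.0)
    baseline_meanlog: float = math.log(100.0)
    baseline_sdlog: float = 1.0
    dispersion: float = 0.0
    de_fraction: float = 0.0
    fold_change: float = 1.0
    read_length: int = 35
    seed: int = 2010

    def __post_init__(self) -> None:
        if self.m_genes < 1 or self.n_samples < 2 or self.n_groups < 1:
            raise ValueError("need >= 1 gene, >= 2 samples, >= 1 group")
        if self.depth_range[0] <= 0 or self.depth_range[1] < self.depth_range[0]:
            raise ValueError("depth_range must be positive and ordered")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if not 0 <= self.de_fraction <= 1:
            raise ValueError("de_fraction must lie in [0, 1]")
        if self.fold_change <= 0 or self.baseline_sdlog < 0 or self.read_length < 1:
            raise ValueError("invalid fold change, baseline sd, or read length")


def _draw_structure(config: SimulationConfig, rng: np.random.Generator):
    """Shared draws: sample labels, depths, baselines, DE assignment, means."""
    n, m = config.n_samples, config.m_genes
    groups = [chr(ord("A") + g % 26) for g in range(config.n_groups)]
    labels = np.array([groups[j % config.n_groups] for j in range(n)], dtype=object)
    rng.shuffle(labels)  # random assignment of samples to groups
    lo, hi = config.depth_range
    d = np.exp(rng.uniform(math.log(lo), math.log(hi), size=n))
    lam = rng.lognormal(config.baseline_meanlog, config.baseline_sdlog, size=m)
    n_de = int(round(config.de_fraction * m))
    de_idx = rng.choice(m, size=n_de, replace=False) if n_de else np.array([], dtype=int)
    is_de = np.zeros(m, dtype=bool)
    is_de[de_idx] = True
    fold = np.ones((m, n))
    if n_de and config.n_groups >= 2:
        in_group2 = labels == groups[1]
        fold[np.ix_(is_de, in_group2)] = config.fold_change
    mu = d[None, :] * lam[:, None] * fold
    return labels, d, lam, is_de, mu


def _draw_counts(mu: np.ndarray, phi: float, rng: np.random.Generator) -> np.ndarray:
    if phi == 0.0:
        return rng.poisson(mu)
    rate = rng.gamma(shape=1.0 / phi, scale=mu * phi)
    return rng.poisson(rate)


def simulate_counts(config: SimulationConfig) -> tuple[CountMatrix, pd.DataFrame]:
    """Draw a gene x sample count matrix plus a truth table.

    Returns the :class:`CountMatrix` (with group labels attached) and a
    DataFrame of per-gene truth: baseline mean, DE status, fold change.
    Deterministic for a given seed.
    """
    rng = np.random.default_rng(config.seed)
    labels, d, lam, is_de, mu = _draw_structure(config, rng)
    counts = _draw_counts(mu, config.dispersion, rng)
    genes = [f"G{i + 1:06d}" for i in range(config.m_genes)]
    samples = [f"s{j + 1:03d}" for j in range(config.n_samples)]
    cm = CountMatrix(genes, samples, counts, dict(zip(samples, labels)))
    truth = pd.DataFrame(
        {
            "gene_id": genes,
            "baseline_mean": lam,
            "is_de": is_de,
            "fold_change": np.where(is_de, config.fold_change, 1.0),
        }
    )
    return cm, truth


# ---------------------------------------------------------------------------
# annotation + alignment fixtures


def simulate_annotation(
    n_genes: int = 5,
    n_transcripts: int = 3,
    seed: int = 2010,
    chrom: str = "chrS",
    exon_len: int = 200,
    n_exons: int = 4,
    gap: int = 500,
) -> str:
    """A toy GTF with multi-transcript genes sharing and varying exons.

    Each gene has ``n_exons`` candidate exons; every transcript keeps
    the first and last (shared/constitutive) and includes each interior
    exon with probability 1/2 (variable), so union and
    union-intersection models genuinely differ.
    """
    rng = np.random.default_rng(seed)
    lines = []
    pos = 1000
    for g in range(n_genes):
        gid = f"G{g + 1:03d}"
        strand = "+" if rng.random() < 0.5 else "-"
        exons = []
        for _ in range(n_exons):
            exons.append((pos, pos + exon_len))
            pos += exon_len + int(rng.integers(50, 300))
        for t in range(n_transcripts):
            tid = f"{gid}.T{t + 1}"
            keep = [exons[0]] + [e for e in exons[1:-1] if rng.random() < 0.5] + [exons[-1]]
            for s, e in keep:  # GTF is 1-based closed
                lines.append(
                    f"{chrom}\tsim\texon\t{s + 1}\t{e}\t.\t{strand}\t.\t"
                    f'gene_id "{gid}"; transcript_id "{tid}";'
                )
        pos += gap
    return "\n".join(lines) + "\n"


def simulate_alignments(
    models: Sequence[GeneIntervalSet],
    config: SimulationConfig,
    sink: str | TextIO,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Write a SAM file whose reads anchor inside the given gene models.

    Per (gene, sample) a read count is drawn exactly as in
    :func:`simulate_counts`; each read's 3'-most base is placed
    uniformly over the gene's interval set, with random strand, tagged
    with its sample's read group. Returns the planted per-gene counts
    (the ground truth an overlap counter should recover) and the truth
    table. Zero-length genes are skipped. Byte-identical SAM for a
    given seed.
    """
    usable = [m for m in models if m.length > 0]
    if not usable:
        raise ValueError("no non-empty gene models to simulate from")
    cfg = replace(config, m_genes=len(usable))
    rng = np.random.default_rng(cfg.seed)
    labels, d, lam, is_de, mu = _draw_structure(cfg, rng)
    counts = _draw_counts(mu, cfg.dispersion, rng)

    samples = [f"s{j + 1:03d}" for j in range(cfg.n_samples)]
    chrom_len: dict[str, int] = {}
    for m in usable:
        end = m.intervals[-1].end + cfg.read_length + 1
        chrom_len[m.chrom] = max(chrom_len.get(m.chrom, 0), end)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": chrom_len[c]} for c in sorted(chrom_len)],
        "RG": [{"ID": s, "SM": s} for s in samples],
    }
    refs = {c: i for i, c in enumerate(sorted(chrom_len))}

    own_handle = isinstance(sink, str)
    out = pysam.AlignmentFile(sink, "w", header=header)
    try:
        rid = 0
        for gi, gm in enumerate(usable):
            # cumulative base offsets map a uniform base index to a coordinate
            spans = gm.spans()
            cum = np.cumsum([0] + [e - s for s, e in spans])
            for sj, smp in enumerate(samples):
                for _ in range(int(counts[gi, sj])):
                    base = int(rng.integers(0, gm.length))
                    k = int(np.searchsorted(cum, base, side="right") - 1)
                    anchor = spans[k][0] + (base - int(cum[k]))
                    minus = bool(rng.random() < 0.5)
                    if minus:
                        start, end = anchor, anchor + cfg.read_length
                    else:
                        start = max(0, anchor - cfg.read_length + 1)
                        end = anchor + 1
                    a = pysam.AlignedSegment(header=pysam.AlignmentHeader.from_dict(header))
                    a.query_name = f"r{rid:08d}"
                    a.reference_id = refs[gm.chrom]
                    a.reference_start = start
                    a.flag = 16 if minus else 0
                    a.mapping_quality = 255
                    a.cigarstring = f"{end - start}M"
                    a.query_sequence = "A" * (end - start)
                    a.query_qualities = pysam.qualitystring_to_array("I" * (end - start))
                    a.set_tag("RG", smp)
                    a.set_tag("NH", 1)
                    out.write(a)
                    rid += 1
    finally:
        out.close()

    genes = [m.gene_id for m in usable]
    cm = CountMatrix(genes, samples, counts, dict(zip(samples, labels)))
    truth = pd.DataFrame(
        {
            "gene_id": genes,
            "baseline_mean": lam,
            "is_de": is_de,
            "fold_change": np.where(is_de, cfg.fold_change, 1.0),
        }
    )
    return cm, truth


# ---------------------------------------------------------------------------
# calibration experiment


def expected_significant(m: int, alpha: float) -> int:
    """Expected number of significant genes under a uniform null: alpha * m."""
    return int(round(alpha * m))


@dataclass
class CalibrationReport:
    """Per-strategy rejection fractions plus p-value histogram tables."""

    table: pd.DataFrame
    histograms: dict[str, pd.DataFrame] = field(default_factory=dict)

    def fraction(self, family: str, norm_mode: str, inference: str, alpha: float) -> float:
        t = self.table
        row = t[
            (t.family == family)
            & (t.norm_mode == norm_mode)
            & (t.inference == inference)
            & (t.alpha == alpha)
        ]
        if row.empty:
            raise KeyError((family, norm_mode, inference, alpha))
        return float(row.fraction_significant.iloc[0])


def null_calibration_experiment(
    config: SimulationConfig,
    strategies: Sequence[tuple[str, str, str]] = STRATEGIES,
    alphas: Sequence[float] = (0.01, 0.05),
    B: int = 20,
    histogram_bins: int = 20,
) -> CalibrationReport:
    """Run the randomized-label calibration experiment.

    Simulates counts under the configured replication model (the global
    null unless ``de_fraction`` > 0 requests a power run), filters
    unexpressed genes, computes 75th-percentile factors, runs every
    requested strategy and reports, per strategy and alpha: the fraction
    and count of genes with p < alpha and the count expected under a
    uniform null. Histogram tables of the p-values are attached per
    strategy.
    """
    from .summarize import pvalue_histogram

    cm, _ = simulate_counts(config)
    cm = normalize.filter_expressed_genes(cm)
    factors = normalize.normalization_factors(cm)
    labels = cm.label_vector()
    m = cm.m

    rows = []
    hists: dict[str, pd.DataFrame] = {}
    for family, norm_mode, inference in strategies:
        spec = de_stats.ModelSpec(family="gaussian" if family == "permutation" else family,
                                  norm_mode=norm_mode)
        designs = de_stats.design_matrix(labels, factors, spec)
        D, p_asym, _ = de_stats.lrt_all(cm.counts, designs, spec)
        if inference == "permutation":
            nulls = de_stats.permute_null(
                cm, labels, factors, spec, B=B, seed=config.seed + 1
            )
            p = de_stats.permutation_pvalues(D, nulls)
        else:
            p = p_asym
        key = f"{family}_{norm_mode}_{inference}"
        hists[key] = pvalue_histogram(p, bins=histogram_bins)
        for alpha in alphas:
            n_sig = int((p < alpha).sum())
            rows.append(
                {
                    "family": family,
                    "norm_mode": norm_mode,
                    "inference": inference,
                    "alpha": alpha,
                    "m": m,
                    "n_significant": n_sig,
                    "fraction_significant": n_sig / m,
                    "expected_significant": expected_significant(m, alpha),
                }
            )
    return CalibrationReport(pd.DataFrame(rows), hists)
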