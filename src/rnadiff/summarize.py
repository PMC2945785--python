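"""Experiment-level summaries: q-values, gene ranking, RPKM tables.

Q-values are Benjamini-Hochberg step-up FDR adjustments (optionally
scaled by a π0 estimate); RPKM normalizes counts by gene model length
and sequencing depth; top-N ranking keeps all genes tied at the cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, TextIO

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .de_stats import TestResult
from .gene_models import GeneIntervalSet
from .overlap_counter import CountMatrix, OverlapRecord

__all__ = [
    "qvalues",
    "rpkm_table",
    "top_genes",
    "pvalue_histogram",
    "filter_overlaps_to_top",
    "results_table",
]


def qvalues(pvals: Sequence[float] | np.ndarray, pi0: float = 1.0) -> np.ndarray:
    """FDR step-up adjusted p-values, in the input order.

    q_(i) = min_{j >= i} (pi0 * m * p_(j) / j), capped at 1. With
    pi0 = 1 this is the classical Benjamini-Hochberg adjustment.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    if not 0 < pi0 <= 1:
        raise ValueError("pi0 must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return np.minimum(q * pi0, 1.0)


def rpkm_table(
    counts: CountMatrix,
    models: Sequence[GeneIntervalSet],
    depth_totals: Sequence[float] | np.ndarray | None = None,
) -> pd.DataFrame:
    """RPKM_ij = c_ij / ((L_i / 1e3) * (N_j / 1e6)).

    L_i is the gene model length; N_j defaults to the sample's total
    assigned reads (column sum) but may be supplied externally (e.g.
    total uniquely aligned reads). Zero-length genes get NaN.
    """
    lengths = {m.gene_id: m.length for m in models}
    L = np.array([lengths.get(g, 0) for g in counts.genes], dtype=float)
    if depth_totals is None:
        N = counts.counts.sum(axis=0).astype(float)
    else:
        N = np.asarray(depth_totals, dtype=float)
    if (N <= 0).any():
        bad = [s for s, v in zip(counts.samples, N) if v <= 0]
        raise ValueError(f"non-positive depth total for sample(s) {bad}")
    with np.errstate(divide="ignore", invalid="ignore"):
        rpkm = counts.counts / ((L[:, None] / 1e3) * (N[None, :] / 1e6))
    rpkm[L == 0, :] = np.nan
    df = pd.DataFrame(rpkm, index=counts.genes, columns=counts.samples)
    df.index.name = "gene_id"
    return df


def top_genes(results: Sequence[TestResult], N: int) -> list[TestResult]:
    """The N smallest-p genes, ties at the cutoff included.

    Sorting is by p ascending with gene_id as the deterministic
    tie-break; every gene whose p equals the Nth smallest p is returned,
    so the list may exceed N.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    ranked = sorted(results, key=lambda r: (r.p_asymptotic, r.gene_id))
    if N >= len(ranked):
        return ranked
    cutoff = ranked[N - 1].p_asymptotic
    out = list(ranked[:N])
    for r in ranked[N:]:
        if r.p_asymptotic == cutoff:
            out.append(r)
        else:
            break
    return out


def pvalue_histogram(pvals: Sequence[float] | np.ndarray, bins: int = 20) -> pd.DataFrame:
    """Equal-width histogram of p-values on [0, 1] as a data table."""
    counts, edges = np.histogram(np.asarray(pvals, dtype=float), bins=bins, range=(0.0, 1.0))
    return pd.DataFrame({"bin_start": edges[:-1], "bin_end": edges[1:], "count": counts})


def filter_overlaps_to_top(
    records: Sequence[OverlapRecord], top: Sequence[TestResult]
) -> list[OverlapRecord]:
    """Keep only overlap records belonging to top-ranked genes."""
    keep = {r.gene_id for r in top}
    return [r for r in records if r.gene_id in keep]


def results_table(results: Sequence[TestResult], qvals: np.ndarray | None = None) -> pd.DataFrame:
    """Per-gene results as a DataFrame (gene order preserved)."""
    df = pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in results],
            "D": [r.D for r in results],
            "df": [r.df for r in results],
            "p_asymptotic": [r.p_asymptotic for r in results],
            "p_permutation": [r.p_permutation for r in results],
            "converged": [r.converged for r in results],
        }
    )
    if qvals is not None:
        df["q"] = qvals
    return df
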