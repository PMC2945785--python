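"""Expression filtering and per-sample normalization factors.

The default factor is the 75th percentile of a sample's *non-zero* gene
counts (upper-quartile normalization); the median or the total count are
alternatives. Factors feed the statistics stage as an offset or as an
estimated model term.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence, TextIO

import numpy as np
import pandas as pd

from .overlap_counter import CountMatrix

logger = logging.getLogger("rnadiff")

__all__ = [
    "NormalizationFactors",
    "filter_expressed_genes",
    "normalization_factor",
    "normalization_factors",
]


@dataclass
class NormalizationFactors:
    """Per-sample positive factors q_j plus the method that produced them."""

    samples: list[str]
    values: np.ndarray
    method: str = "quantile:0.75"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.samples):
            raise ValueError("one factor per sample required")
        if (self.values <= 0).any():
            bad = [s for s, v in zip(self.samples, self.values) if v <= 0]
            raise ValueError(f"non-positive normalization factor for {bad}")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.samples, self.values))

    def to_tsv(self, sink: str | TextIO) -> None:
        df = pd.DataFrame({"sample": self.samples, "method": self.method, "value": self.values})
        df.to_csv(sink, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, source: str | TextIO) -> "NormalizationFactors":
        df = pd.read_csv(source, sep="\t")
        return cls(list(df["sample"].astype(str)), df["value"].to_numpy(), str(df["method"].iloc[0]))


def filter_expressed_genes(counts: CountMatrix) -> CountMatrix:
    """Drop genes with zero counts in every sample; keep gene order.

    A single read anywhere is enough to retain a gene. Raises if the
    filter would leave nothing to test.
    """
    totals = counts.counts.sum(axis=1)
    keep = totals > 0
    if not keep.any():
        raise ValueError("all genes have zero counts; nothing to test")
    dropped = int((~keep).sum())
    if dropped:
        logger.info("expression filter removed %d of %d genes", dropped, counts.m)
    return CountMatrix(
        genes=[g for g, k in zip(counts.genes, keep) if k],
        samples=list(counts.samples),
        counts=counts.counts[keep],
        labels=dict(counts.labels),
    )


def normalization_factor(
    column: Sequence[float] | np.ndarray,
    method: str = "quantile",
    p: float = 0.75,
    interpolation: str = "linear",
) -> float:
    """Normalization factor for one sample's gene-count column.

    ``quantile`` (default p = 0.75) and ``median`` act on the multiset of
    non-zero counts; ``total`` sums everything, zeros included. The
    quantile interpolates linearly between order statistics by default;
    ``interpolation="nearest_rank"`` selects the ceil(p·n)-th order
    statistic instead.
    """
    col = np.asarray(column, dtype=float)
    if method == "total":
        tot = float(col.sum())
        if tot <= 0:
            raise ValueError("total count is zero; no normalization factor")
        return tot
    if method == "median":
        method, p = "quantile", 0.5
    if method != "quantile":
        raise ValueError(f"unknown normalization method {method!r}")
    nz = col[col > 0]
    if nz.size == 0:
        raise ValueError("sample has no non-zero gene counts")
    interp = {"linear": "linear", "nearest_rank": "inverted_cdf"}[interpolation]
    return float(np.quantile(nz, p, method=interp))


def normalization_factors(
    counts: CountMatrix,
    method: str = "quantile",
    p: float = 0.75,
    interpolation: str = "linear",
) -> NormalizationFactors:
    """Compute one factor per sample of a count matrix."""
    vals = []
    for j, s in enumerate(counts.samples):
        try:
            vals.append(normalization_factor(counts.counts[:, j], method, p, interpolation))
        except ValueError as exc:
            raise ValueError(f"sample {s!r}: {exc}") from exc
    desc = method if method != "quantile" else f"quantile:{p:g}"
    return NormalizationFactors(list(counts.samples), np.array(vals), desc)
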