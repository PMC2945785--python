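"""Per-gene differential-expression tests.

The model relates gene counts c_ij to a per-sample outcome y_j through a
generalized linear model

    g(E[f(c_ij) | y_j]) = b_i0 + eta_i * log(q_j) + sum_k b_ik s_k(y_j)

with g the link (log for the Poisson family, identity for Gaussian) and
f the count transform (identity for Poisson, log for Gaussian). q_j is
the per-sample normalization factor; it enters either as a fixed offset
(eta_i = 1 for all genes) or as an estimated model term. The outcome is
a K-group factor (reference-level dummies, K-1 test columns) or a
continuous covariate (one column).

Differential expression for gene i is the likelihood-ratio statistic
D_i = 2 (loglik_full - loglik_null); inference is the asymptotic
chi-square tail or a pooled permutation null: labels are permuted B
times, the identical fit is repeated, and

    p_i = (#{D_j^0b > D_i over all genes j and permutations b} + 1) / (m B + 1)

so null statistics are pooled across genes. Poisson fits use iteratively
reweighted least squares, vectorized across genes; Gaussian fits are
least squares on log(c + pseudocount) with the profile log-likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import special, stats

from .normalize import NormalizationFactors
from .overlap_counter import CountMatrix

__all__ = [
    "ModelSpec",
    "Designs",
    "FittedGeneModel",
    "TestResult",
    "NullStatistics",
    "design_matrix",
    "fit_and_lrt",
    "lrt_all",
    "permute_null",
    "permutation_pvalues",
]

_IRLS_TOL = 1e-8
_IRLS_MAXITER = 50
_P_FLOOR = 1e-300  # p-values live in (0, 1]


@dataclass
class ModelSpec:
    """Family, normalization mode and outcome handling for the GLM.

    family        "poisson" (log link, identity transform) or "gaussian"
                  (identity link, log transform with ``pseudocount``).
    norm_mode     "offset": log(q_j) enters with coefficient fixed at 1;
                  "term": log(q_j) is a column with estimated
                  gene-specific coefficient (a nuisance under both
                  hypotheses).
    outcome       "factor" (grouped samples) or "continuous".
    gaussian_test "lrt" (default) or "ttest" for the single-contrast
                  two-sided regression t-test on transformed counts.
    """

    family: str = "poisson"
    norm_mode: str = "offset"
    outcome: str = "factor"
    pseudocount: float = 0.5
    gaussian_test: str = "lrt"

    def __post_init__(self) -> None:
        if self.family not in ("poisson", "gaussian"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.norm_mode not in ("offset", "term"):
            raise ValueError(f"unknown norm_mode {self.norm_mode!r}")
        if self.outcome not in ("factor", "continuous"):
            raise ValueError(f"unknown outcome kind {self.outcome!r}")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        if self.gaussian_test not in ("lrt", "ttest"):
            raise ValueError(f"unknown gaussian_test {self.gaussian_test!r}")


@dataclass
class Designs:
    """Full/null design matrices, shared offset vector and test df."""

    X_full: np.ndarray
    X_null: np.ndarray
    offset: np.ndarray
    df: int
    levels: list[object] = field(default_factory=list)


@dataclass
class FittedGeneModel:
    """Coefficients and log-likelihoods of one gene's full and null fits."""

    coef_full: np.ndarray
    coef_null: np.ndarray
    loglik_full: float
    loglik_null: float
    converged: bool


@dataclass
class TestResult:
    __test__ = False  # not a pytest class despite the name

    gene_id: str
    D: float
    df: int
    p_asymptotic: float
    p_permutation: float | None = None
    converged: bool = True


@dataclass
class NullStatistics:
    """m × B matrix of statistics from B global label permutations."""

    matrix: np.ndarray
    permutations: np.ndarray  # B × n index permutations applied to labels
    seed: int

    @property
    def B(self) -> int:
        return self.matrix.shape[1]


# ---------------------------------------------------------------------------
# design


def design_matrix(
    labels: Sequence[object],
    factors: NormalizationFactors | np.ndarray,
    spec: ModelSpec,
) -> Designs:
    """Build full and null designs from outcome labels and factors q_j.

    The full design holds an intercept, log(q_j) in term mode, and the
    outcome columns (K-1 reference-level dummies for a K-group factor,
    one column for a continuous outcome). The null design drops only the
    outcome columns. In offset mode log(q_j) is returned as the shared
    offset vector instead of a column.
    """
    q = factors.values if isinstance(factors, NormalizationFactors) else np.asarray(factors, dtype=float)
    if (q <= 0).any():
        raise ValueError("normalization factors must be positive")
    n = len(q)
    if len(labels) != n:
        raise ValueError("labels and factors disagree on sample count")
    logq = np.log(q)

    base = [np.ones(n)]
    offset = np.zeros(n)
    if spec.norm_mode == "offset":
        offset = logq
    else:
        if np.ptp(logq) == 0.0:
            import logging

            logging.getLogger("rnadiff").warning(
                "log(q_j) constant across samples; normalization term dropped"
            )
        else:
            base.append(logq)

    levels: list[object] = []
    if spec.outcome == "factor":
        levels = sorted(set(labels), key=str)
        if len(levels) < 2:
            raise ValueError("outcome has a single level: no contrast to test")
        cols = [
            np.array([1.0 if y == lev else 0.0 for y in labels]) for lev in levels[1:]
        ]
    else:
        y = np.asarray(labels, dtype=float)
        if np.ptp(y) == 0.0:
            raise ValueError("continuous outcome is constant: no contrast to test")
        cols = [y]

    X_null = np.column_stack(base)
    X_full = np.column_stack(base + cols)
    return Designs(X_full, X_null, offset, df=len(cols), levels=levels)


# ---------------------------------------------------------------------------
# Poisson: batched IRLS


def _poisson_deviance(C: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """2 * sum[c log(c/mu) - (c - mu)] with the 0*log(0) := 0 convention."""
    term = special.xlogy(C, C) - special.xlogy(C, mu) - (C - mu)
    return 2.0 * term.sum(axis=1)


def _poisson_loglik(C: np.ndarray, mu: np.ndarray) -> np.ndarray:
    return (special.xlogy(C, mu) - mu - special.gammaln(C + 1.0)).sum(axis=1)


def _irls_poisson(
    C: np.ndarray, X: np.ndarray, offset: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit m independent Poisson regressions sharing design X.

    Returns (beta (m,p), deviance (m,), converged (m,)). Iterations stop
    per-gene when the deviance change falls below ``_IRLS_TOL`` relative
    tolerance, or at ``_IRLS_MAXITER``.
    """
    C = np.asarray(C, dtype=float)
    m, n = C.shape
    p = X.shape[1]
    mu = C + 0.5  # standard IRLS initialization
    eta = np.log(mu) - offset
    beta = np.zeros((m, p))
    dev = np.full(m, np.inf)
    converged = np.zeros(m, dtype=bool)
    active = np.ones(m, dtype=bool)

    for _ in range(_IRLS_MAXITER):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        W = mu[idx]  # (a, n) working weights
        z = eta[idx] + (C[idx] - mu[idx]) / mu[idx]  # working response
        # per-gene weighted normal equations, batched
        A = np.einsum("ni,an,nj->aij", X, W, X)
        b = np.einsum("ni,an->ai", X, W * z)
        try:
            beta_new = np.linalg.solve(A, b[..., None])[..., 0]
        except np.linalg.LinAlgError:
            beta_new = np.stack([np.linalg.lstsq(Ai, bi, rcond=None)[0] for Ai, bi in zip(A, b)])
        eta_new = np.clip(beta_new @ X.T, -30.0, 30.0)
        mu_new = np.exp(eta_new + offset)
        dev_new = _poisson_deviance(C[idx], mu_new)

        beta[idx] = beta_new
        eta[idx] = eta_new
        mu[idx] = mu_new
        done = np.abs(dev[idx] - dev_new) <= _IRLS_TOL * (np.abs(dev_new) + 0.1)
        dev[idx] = dev_new
        converged[idx[done]] = True
        active[idx[done]] = False
    return beta, dev, converged


# ---------------------------------------------------------------------------
# Gaussian: batched least squares


def _ols_rss(Z: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares coefficients and residual sums of squares, all genes."""
    beta, _, _, _ = np.linalg.lstsq(X, Z.T, rcond=None)
    resid = Z.T - X @ beta
    return beta.T, (resid**2).sum(axis=0)


def _gaussian_profile_loglik(rss: np.ndarray, n: int) -> np.ndarray:
    rss = np.maximum(rss, 1e-300)
    return -0.5 * n * (np.log(2.0 * np.pi * rss / n) + 1.0)


# ---------------------------------------------------------------------------
# LRT


def lrt_all(
    counts: np.ndarray, designs: Designs, spec: ModelSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Likelihood-ratio statistics and asymptotic p-values for all genes.

    Returns (D (m,), p (m,), converged (m,)). D is clamped at zero; the
    p-value is the upper chi-square tail with ``designs.df`` degrees of
    freedom (floored at a tiny positive value so p stays in (0, 1]).
    """
    C = np.asarray(counts, dtype=float)
    if C.ndim == 1:
        C = C[None, :]
    if (C < 0).any():
        raise ValueError("negative counts")
    m, n = C.shape

    if spec.family == "poisson":
        if not np.allclose(C, np.round(C)):
            raise ValueError("poisson family requires integer counts")
        _, dev_full, conv_f = _irls_poisson(C, designs.X_full, designs.offset)
        _, dev_null, conv_n = _irls_poisson(C, designs.X_null, designs.offset)
        D = dev_null - dev_full
        converged = conv_f & conv_n
    else:
        Z = np.log(C + spec.pseudocount) - designs.offset
        if spec.gaussian_test == "ttest":
            return _gaussian_ttest(Z, designs)
        _, rss_full = _ols_rss(Z, designs.X_full)
        _, rss_null = _ols_rss(Z, designs.X_null)
        tiny = 1e-12 * n
        both_perfect = (rss_full <= tiny) & (rss_null <= tiny)
        D = n * np.log(np.maximum(rss_null, 1e-300) / np.maximum(rss_full, 1e-300))
        D = np.where(both_perfect, 0.0, D)
        converged = np.ones(m, dtype=bool)

    D = np.maximum(D, 0.0)
    p = np.maximum(stats.chi2.sf(D, designs.df), _P_FLOOR)
    return D, p, converged


def _gaussian_ttest(Z: np.ndarray, designs: Designs) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Two-sided regression t-test on the single outcome column.

    The squared t statistic is reported in place of D so that ranking
    and permutation machinery apply unchanged.
    """
    if designs.df != 1:
        raise ValueError("t-test applies to a single-contrast design (df = 1)")
    X = designs.X_full
    n, pdim = X.shape
    if n <= pdim:
        raise ValueError("t-test requires more samples than parameters")
    beta, rss = _ols_rss(Z, X)
    sigma2 = rss / (n - pdim)
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[-1, -1], 1e-300))
    t = beta[:, -1] / se
    p = np.maximum(2.0 * stats.t.sf(np.abs(t), n - pdim), _P_FLOOR)
    return t**2, p, np.ones(Z.shape[0], dtype=bool)


def fit_and_lrt(
    counts_row: Sequence[float] | np.ndarray,
    designs: Designs,
    spec: ModelSpec,
    gene_id: str = "",
) -> TestResult:
    """Test one gene's counts; see :func:`lrt_all` for the statistic."""
    row = np.asarray(counts_row, dtype=float)
    if row.ndim != 1 or row.size != designs.X_full.shape[0]:
        raise ValueError("counts row length must equal the number of samples")
    D, p, conv = lrt_all(row[None, :], designs, spec)
    return TestResult(gene_id, float(D[0]), designs.df, float(p[0]), converged=bool(conv[0]))


# ---------------------------------------------------------------------------
# permutation inference


def permute_null(
    counts: CountMatrix | np.ndarray,
    labels: Sequence[object],
    factors: NormalizationFactors | np.ndarray,
    spec: ModelSpec,
    B: int,
    seed: int,
) -> NullStatistics:
    """Null statistics from B global label permutations.

    One permutation per b is shared across all genes (cross-gene
    structure is preserved); each permuted design is refit with the
    identical procedure that produced the observed statistics.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    C = counts.counts if isinstance(counts, CountMatrix) else np.asarray(counts)
    labels_arr = np.asarray(labels, dtype=object)
    n = len(labels_arr)
    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(n) for _ in range(B)])
    cols = []
    for b in range(B):
        designs_b = design_matrix(labels_arr[perms[b]], factors, spec)
        D_b, _, _ = lrt_all(C, designs_b, spec)
        cols.append(D_b)
    return NullStatistics(np.column_stack(cols), perms, seed)


def permutation_pvalues(
    observed: Sequence[float] | np.ndarray, nulls: NullStatistics | np.ndarray
) -> np.ndarray:
    """Pooled permutation p-values: p_i = (#{null > D_i} + 1) / (mB + 1).

    The exceedance count pools the whole m × B null matrix and uses
    strict inequality (ties do not count). Computed by sorting the null
    statistics once and scanning the observed list against them.
    """
    D = np.asarray(observed, dtype=float)
    null_mat = nulls.matrix if isinstance(nulls, NullStatistics) else np.asarray(nulls)
    flat = np.sort(null_mat, axis=None)
    total = flat.size
    if total == 0:
        raise ValueError("empty null statistic matrix")
    greater = total - np.searchsorted(flat, D, side="right")
    return (greater + 1.0) / (total + 1.0)
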