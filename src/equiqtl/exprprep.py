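"""Expression preparation: filtration, normalization, residualization.

Low-expression genes are removed with an iterative Kolmogorov-Smirnov
procedure: for every pair of samples, candidate mean-count cutoffs are
walked over a fixed grid (0..300 step 2) and at each step the two-sample
D statistic between the pair's retained expression profiles is evaluated;
the walk stops at the first cutoff whose D has dropped clearly below the
starting D (see :func:`ks_cutoff_pair` for the three stopping rules).  The
cohort-level cutoff is the mean of all pairwise cutoffs.

Counts are normalized with median-of-ratios size factors and variance
stabilized with log2(normalized + 1) — a deliberately simple transform
that preserves the monotonicity and variance-flattening the scan needs.
Known covariates plus PCA-derived latent factors are then regressed out
gene by gene to produce the residual matrix the eQTL scan consumes.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import CountMatrix

logger = logging.getLogger(__name__)

KS_GRID = tuple(range(0, 301, 2))
KS_MARGIN = 1e-4


@dataclass
class ExpressionMatrix:
    """Genes x samples variance-stabilized expression with size factors."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    size_factors: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.size_factors = np.asarray(self.size_factors, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("values shape inconsistent with ids")
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite expression values")
        if (self.size_factors <= 0).any():
            raise ValueError("size factors must be positive")


@dataclass
class KsCutoffResult:
    """Cohort-level outcome of the pairwise KS cutoff search."""

    pairwise_cutoffs: dict[tuple[str, str], int]
    unresolved_pairs: list[tuple[str, str]]
    mean_cutoff: float
    median_cutoff: float
    genes_retained: list[str]


@dataclass
class ResidualMatrix:
    """Covariate- and latent-factor-free expression residuals."""

    gene_ids: list[str]
    sample_ids: list[str]
    residuals: np.ndarray
    k_factors: int
    covariates_used: list[str]
    factors: np.ndarray | None = None  # k x samples latent factor scores

    def __post_init__(self) -> None:
        self.residuals = np.asarray(self.residuals, dtype=float)
        if self.residuals.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("residual shape inconsistent with ids")


def size_factors(counts: CountMatrix) -> np.ndarray:
    """Median-of-ratios normalization factors, one per sample.

    The reference for gene g is the geometric mean of its counts across
    samples (genes with a zero anywhere are excluded); factor_j is the
    median over reference genes of count_gj / reference_g.
    """
    c = counts.counts.astype(float)
    all_pos = (c > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError(
            "no gene has nonzero counts in every sample; "
            "cannot form a geometric-mean reference (consider a pseudo-reference)"
        )
    ref = np.exp(np.log(c[all_pos]).mean(axis=1))
    factors = np.median(c[all_pos] / ref[:, None], axis=0)
    if not (np.isfinite(factors).all() and (factors > 0).all()):
        raise ValueError("degenerate size factors")
    return factors


def normalized_counts(counts: CountMatrix, factors: np.ndarray | None = None):
    if factors is None:
        factors = size_factors(counts)
    return counts.counts / factors[None, :], factors


def vst(counts: CountMatrix, factors: np.ndarray) -> ExpressionMatrix:
    """Variance-stabilized expression: log2(count / size_factor + 1)."""
    if (counts.counts < 0).any():
        raise ValueError("negative counts")
    values = np.log2(counts.counts / np.asarray(factors)[None, :] + 1.0)
    return ExpressionMatrix(
        gene_ids=list(counts.gene_ids),
        sample_ids=list(counts.sample_ids),
        values=values,
        size_factors=np.asarray(factors, dtype=float),
    )


def _ks_d(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sample Kolmogorov-Smirnov D statistic (sup ECDF distance)."""
    a = np.sort(a)
    b = np.sort(b)
    grid = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, grid, side="right") / a.size
    cdf_b = np.searchsorted(b, grid, side="right") / b.size
    return float(np.abs(cdf_a - cdf_b).max())


def ks_cutoff_pair(
    expr_a: np.ndarray,
    expr_b: np.ndarray,
    grid: tuple[int, ...] = KS_GRID,
) -> tuple[int, bool]:
    """Walk the cutoff grid for one sample pair; return (cutoff, resolved).

    At each candidate cutoff, genes whose pair-mean normalized count falls
    below the cutoff are dropped and the KS D statistic between the two
    retained expression profiles is computed.  The walk stops at cutoff c_i
    when (i) D_i < D_0, (ii) D_i < D_{i+1}, and (iii) D_i < D_0 - 1e-4.
    If the rules are never satisfied (or fewer than 2 genes remain) the
    grid maximum is returned with resolved=False.
    """
    expr_a = np.asarray(expr_a, dtype=float)
    expr_b = np.asarray(expr_b, dtype=float)
    if expr_a.shape != expr_b.shape:
        raise ValueError("pair profiles must share a gene set")
    pair_mean = (expr_a + expr_b) / 2.0

    d_stats: list[float] = []

    def d_at(idx: int) -> float:
        while len(d_stats) <= idx:
            step = len(d_stats)
            keep = pair_mean >= grid[step]
            if keep.sum() < 2:
                d_stats.append(np.nan)
            else:
                d_stats.append(_ks_d(expr_a[keep], expr_b[keep]))
        return d_stats[idx]

    d_first = d_at(0)
    if np.isnan(d_first):
        return grid[-1], False
    for i in range(1, len(grid) - 1):
        d_cur = d_at(i)
        if np.isnan(d_cur):
            return grid[-1], False
        d_next = d_at(i + 1)
        if (
            d_cur < d_first
            and (np.isnan(d_next) or d_cur < d_next)
            and d_cur < d_first - KS_MARGIN
        ):
            return grid[i], True
    return grid[-1], False


def ks_cutoff_cohort(
    counts: CountMatrix, factors: np.ndarray | None = None
) -> KsCutoffResult:
    """Run the pairwise KS cutoff search over every unordered sample pair.

    Genes with no reads in any sample are removed up front.  The cohort
    mean cutoff is taken over resolved pairs only; unresolved pairs are
    recorded and logged.  ``genes_retained`` are the pre-filtered genes
    whose mean normalized count is >= the mean cutoff.
    """
    if len(counts.sample_ids) < 2:
        raise ValueError("need at least 2 samples")
    expressed = counts.counts.sum(axis=1) >= 1
    sub = CountMatrix(
        gene_ids=[g for g, keep in zip(counts.gene_ids, expressed) if keep],
        sample_ids=list(counts.sample_ids),
        counts=counts.counts[expressed],
    )
    norm, _ = normalized_counts(sub, factors)
    cutoffs: dict[tuple[str, str], int] = {}
    unresolved: list[tuple[str, str]] = []
    for ia, ib in itertools.combinations(range(len(sub.sample_ids)), 2):
        pair = (sub.sample_ids[ia], sub.sample_ids[ib])
        cutoff, resolved = ks_cutoff_pair(norm[:, ia], norm[:, ib])
        cutoffs[pair] = cutoff
        if not resolved:
            unresolved.append(pair)
    resolved_vals = [
        c for pair, c in cutoffs.items() if pair not in set(unresolved)
    ]
    if unresolved:
        logger.warning(
            "%d of %d sample pairs never satisfied the KS stopping rules",
            len(unresolved), len(cutoffs),
        )
    if resolved_vals:
        mean_cutoff = float(np.mean(resolved_vals))
        median_cutoff = float(np.median(resolved_vals))
    else:
        mean_cutoff = 0.0
        median_cutoff = 0.0
    retained = norm.mean(axis=1) >= mean_cutoff
    return KsCutoffResult(
        pairwise_cutoffs=cutoffs,
        unresolved_pairs=unresolved,
        mean_cutoff=mean_cutoff,
        median_cutoff=median_cutoff,
        genes_retained=[g for g, keep in zip(sub.gene_ids, retained) if keep],
    )


def apply_gene_filter(counts: CountMatrix, gene_ids: list[str]) -> CountMatrix:
    keep = set(gene_ids)
    mask = np.array([g in keep for g in counts.gene_ids])
    return CountMatrix(
        gene_ids=[g for g in counts.gene_ids if g in keep],
        sample_ids=list(counts.sample_ids),
        counts=counts.counts[mask],
    )


def _design_matrix(
    covariates: pd.DataFrame | None, sample_ids: list[str]
) -> tuple[np.ndarray, list[str]]:
    n = len(sample_ids)
    if covariates is None:
        return np.ones((n, 1)), ["intercept"]
    cov = covariates.set_index("sample_id").loc[sample_ids]
    cols = [
        c for c in ("sex", "age", "fam1", "fam2", "status")
        if c in cov.columns and cov[c].nunique() > 1  # constants add nothing
    ]
    X = np.column_stack([np.ones(n)] + [cov[c].to_numpy(dtype=float) for c in cols])
    names = ["intercept"] + cols
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        collinear = []
        kept = [X[:, :1]]
        for j in range(1, X.shape[1]):
            cand = np.column_stack(kept + [X[:, j : j + 1]])
            if np.linalg.matrix_rank(cand) == cand.shape[1]:
                kept.append(X[:, j : j + 1])
            else:
                collinear.append(names[j])
        raise ValueError(f"rank-deficient covariate matrix; collinear: {collinear}")
    return X, names


def _residualize_on(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Least-squares residuals of each row of Y on the columns of X."""
    coef, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    return Y - (X @ coef).T


def residualize(
    expr: ExpressionMatrix,
    covariates: pd.DataFrame | None = None,
    k_factors: int = 10,
    factors: np.ndarray | None = None,
) -> ResidualMatrix:
    """Remove known covariates and latent batch factors from expression.

    Each gene is regressed on an intercept plus the known covariates; the
    top ``k_factors`` principal components of the resulting residual matrix
    serve as latent factors and the regression is repeated with them added.
    Pass ``factors`` explicitly to reuse a previously derived factor basis
    (this makes the operation a fixed projection, hence idempotent).
    """
    Y = expr.values
    X, names = _design_matrix(covariates, expr.sample_ids)
    n = len(expr.sample_ids)
    if factors is None and k_factors >= n - X.shape[1]:
        raise ValueError(
            f"k_factors={k_factors} too large for n={n} with {X.shape[1]} covariates"
        )
    resid0 = _residualize_on(Y, X)
    if factors is None:
        if k_factors > 0:
            _, _, vt = np.linalg.svd(resid0, full_matrices=False)
            factors = vt[:k_factors]
        else:
            factors = np.empty((0, n))
    factors = np.asarray(factors, dtype=float)
    k = factors.shape[0]
    if k > 0:
        X_full = np.column_stack([X, factors.T])
        residuals = _residualize_on(Y, X_full)
    else:
        residuals = resid0
    return ResidualMatrix(
        gene_ids=list(expr.gene_ids),
        sample_ids=list(expr.sample_ids),
        residuals=residuals,
        k_factors=k,
        covariates_used=names,
        factors=factors,
    )
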