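"""Statistical primitives used by every downstream stage.

The two rank tests are implemented from first principles rather than
delegated, because their exact small-sample behaviour is part of this
package's contract:

* :func:`rank_sum_test` — two-sided Mann–Whitney/Wilcoxon rank-sum with
  midranks for ties.  For pooled sizes up to ``exact_limit`` the null
  distribution is enumerated exhaustively over all C(n1+n2, n1) group
  assignments of the observed (tied) ranks; above it a normal approximation
  with tie-corrected variance and a 0.5 continuity correction is used.
* :func:`signed_rank_test` — two-sided Wilcoxon signed-rank on paired
  differences, zero differences dropped.  Exact enumeration over all 2^n
  sign patterns (computed by dynamic programming over the integerised
  midranks) up to ``exact_limit`` informative pairs, normal approximation
  with tie correction beyond.

Two-sided exact p-values are defined as the null probability of a
statistic at least as far from its null mean as observed, which agrees
with brute-force permutation on the raw data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import comb, log

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

__all__ = [
    "TestResult",
    "rank_sum_test",
    "signed_rank_test",
    "adjust_bonferroni",
    "log_fold_change",
    "CorrelationMatrix",
    "correlation_matrix",
    "rank_sum_matrix",
]

RANK_SUM_EXACT_LIMIT = 14  # pooled n1+n2 at or below which the exact null is enumerated
SIGNED_RANK_EXACT_LIMIT = 20  # informative pairs at or below which signs are enumerated
_EPS = 1e-9


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str  # "exact" or "normal_approx"
    n1: int
    n2: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value out of [0,1]: {self.p_value}")


# ---------------------------------------------------------------------------
# rank-sum (Mann–Whitney / Wilcoxon two-sample)
# ---------------------------------------------------------------------------

def rank_sum_test(
    x, y, exact_limit: int = RANK_SUM_EXACT_LIMIT, force_approx: bool = False
) -> TestResult:
    """Two-sided rank-sum test of ``x`` vs ``y``.

    Returns the Mann–Whitney U of ``x`` as the statistic.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("rank_sum_test requires non-empty groups")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)  # midranks
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0

    if np.all(pooled == pooled[0]):
        return TestResult(statistic=u, p_value=1.0, method="exact", n1=n1, n2=n2)

    if not force_approx and n1 + n2 <= exact_limit:
        p = _rank_sum_exact_p(ranks, n1, u, mu)
        return TestResult(statistic=u, p_value=p, method="exact", n1=n1, n2=n2)

    p = _rank_sum_normal_p(ranks, n1, n2, u, mu)
    return TestResult(statistic=u, p_value=p, method="normal_approx", n1=n1, n2=n2)


def _rank_sum_exact_p(ranks: np.ndarray, n1: int, u_obs: float, mu: float) -> float:
    """Exact p over every assignment of n1 of the observed ranks to group one.

    The full enumeration over C(n, n1) subsets is collapsed into a
    subset-size × rank-sum dynamic program (midranks doubled to integers),
    which counts the identical distribution exactly.
    """
    n = len(ranks)
    r2 = np.round(2 * ranks).astype(int)
    total = int(r2.sum())
    # dp[k, s] = number of k-subsets of the ranks seen so far with doubled sum s
    dp = np.zeros((n1 + 1, total + 1))
    dp[0, 0] = 1.0
    for r in r2:
        dp[1:, r:] += dp[:-1, : total + 1 - r].copy()
    sums = np.arange(total + 1) / 2.0  # back to midrank scale
    u_vals = sums - n1 * (n1 + 1) / 2.0
    dev_obs = abs(u_obs - mu)
    hits = dp[n1, np.abs(u_vals - mu) >= dev_obs - _EPS].sum()
    return float(hits / comb(n, n1))


def _tie_term(ranks: np.ndarray) -> float:
    """Sum of t^3 - t over tie groups of the pooled sample."""
    _, counts = np.unique(ranks, return_counts=True)
    t = counts.astype(float)
    return float(np.sum(t**3 - t))


def _rank_sum_normal_p(
    ranks: np.ndarray, n1: int, n2: int, u: float, mu: float
) -> float:
    n = n1 + n2
    var = n1 * n2 / 12.0 * ((n + 1) - _tie_term(ranks) / (n * (n - 1)))
    if var <= 0:
        return 1.0
    z = max(abs(u - mu) - 0.5, 0.0) / np.sqrt(var)
    return float(min(1.0, 2.0 * norm.sf(z)))


# ---------------------------------------------------------------------------
# signed-rank (Wilcoxon paired)
# ---------------------------------------------------------------------------

def signed_rank_test(
    before, after, exact_limit: int = SIGNED_RANK_EXACT_LIMIT, force_approx: bool = False
) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired ``after - before``.

    Zero differences are dropped; ``n1`` reports informative pairs and
    ``n2`` the dropped (zero) pairs.  The statistic is W+, the sum of the
    ranks of the positive differences.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape:
        raise ValueError("paired samples must have equal length")
    if before.size == 0:
        raise ValueError("signed_rank_test requires at least one pair")
    d = after - before
    n_zero = int(np.sum(d == 0))
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return TestResult(statistic=0.0, p_value=1.0, method="exact", n1=0, n2=n_zero)
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0

    if not force_approx and n <= exact_limit:
        p = _signed_rank_exact_p(ranks, w_plus, mu)
        return TestResult(statistic=w_plus, p_value=p, method="exact", n1=n, n2=n_zero)

    var = n * (n + 1) * (2 * n + 1) / 24.0 - _tie_term(ranks) / 48.0
    if var <= 0:
        p = 1.0
    else:
        z = max(abs(w_plus - mu) - 0.5, 0.0) / np.sqrt(var)
        p = float(min(1.0, 2.0 * norm.sf(z)))
    return TestResult(statistic=w_plus, p_value=p, method="normal_approx", n1=n, n2=n_zero)


def _signed_rank_exact_p(ranks: np.ndarray, w_obs: float, mu: float) -> float:
    """Exact two-sided p over all 2^n sign patterns, via subset-sum counting.

    Midranks are doubled to integers; the distribution of 2·W+ is built by
    convolution, which enumerates every sign pattern implicitly.
    """
    r2 = np.round(2 * ranks).astype(int)
    total = int(r2.sum())
    dist = np.zeros(total + 1, dtype=float)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = dist + shifted
    w_vals = np.arange(total + 1) / 2.0
    dev_obs = abs(w_obs - mu)
    hits = dist[np.abs(w_vals - mu) >= dev_obs - _EPS].sum()
    return float(hits / 2 ** len(ranks))


# ---------------------------------------------------------------------------
# multiplicity and effect size
# ---------------------------------------------------------------------------

def adjust_bonferroni(p, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: min(1, p·m); m defaults to len(p)."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0,1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError(f"m={m} smaller than number of tests {p.size}")
    return np.minimum(1.0, p * m)


def log_fold_change(
    group_mean_expr: float, rest_mean_expr: float, pseudocount: float = 1.0
) -> float:
    """Natural-log fold-change of pseudocounted linear-scale group means."""
    if group_mean_expr < 0 or rest_mean_expr < 0:
        raise ValueError("means must be nonnegative")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    return log((group_mean_expr + pseudocount) / (rest_mean_expr + pseudocount))


# ---------------------------------------------------------------------------
# gene–gene correlation
# ---------------------------------------------------------------------------

@dataclass
class CorrelationMatrix:
    """Symmetric unit-diagonal gene–gene correlation matrix."""

    values: pd.DataFrame
    method: str
    dropped_zero_variance: list[str] = field(default_factory=list)
    missing: list[str] = field(default_factory=list)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)


def correlation_matrix(nm, genes, method: str = "pearson") -> CorrelationMatrix:
    """Pairwise gene–gene correlation across cells of a normalized matrix.

    ``nm`` is any object with ``values`` (genes × cells array) and
    ``gene_symbols``; ``genes`` may be a GeneSet or an iterable of symbols.
    Genes absent from the matrix are warned about and skipped; genes with
    zero variance across cells are excluded and listed.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    symbols = list(getattr(genes, "genes", genes))
    gene_index = {g: i for i, g in enumerate(nm.gene_symbols)}
    missing = [g for g in symbols if g not in gene_index]
    if missing:
        warnings.warn(f"correlation_matrix: {len(missing)} genes absent: {missing[:5]}")
    present = [g for g in symbols if g in gene_index]
    mat = np.asarray(nm.values[[gene_index[g] for g in present], :], dtype=float)
    if hasattr(mat, "toarray"):  # pragma: no cover - sparse input
        mat = mat.toarray()
    if mat.shape[1] < 3:
        raise ValueError("correlation_matrix requires at least 3 cells")
    variances = mat.var(axis=1)
    dropped = [g for g, v in zip(present, variances) if v == 0]
    keep = [g for g, v in zip(present, variances) if v > 0]
    if len(keep) < 2:
        raise ValueError("fewer than 2 usable (non-constant) genes")
    mat = mat[[present.index(g) for g in keep], :]
    if method == "spearman":
        mat = rankdata(mat, axis=1)
    r = np.corrcoef(mat)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    df = pd.DataFrame(r, index=keep, columns=keep)
    return CorrelationMatrix(values=df, method=method, dropped_zero_variance=dropped, missing=missing)


# ---------------------------------------------------------------------------
# vectorised rank-sum over a gene × cell matrix (marker discovery workhorse)
# ---------------------------------------------------------------------------

def rank_sum_matrix(values: np.ndarray, in_mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise two-sided rank-sum of cells in ``in_mask`` vs the rest.

    Uses the same tie-corrected, continuity-corrected normal approximation
    as :func:`rank_sum_test`'s large-sample path (asserted equal in tests).
    Returns ``(U, p)`` arrays, one entry per row of ``values``.
    """
    values = np.asarray(values, dtype=float)
    in_mask = np.asarray(in_mask, dtype=bool)
    n1 = int(in_mask.sum())
    n2 = int((~in_mask).sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    n = n1 + n2
    ranks = rankdata(values, axis=1)
    r1 = ranks[:, in_mask].sum(axis=1)
    u = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    tie = np.empty(values.shape[0])
    srt = np.sort(values, axis=1)
    for i in range(values.shape[0]):  # per-row tie census on presorted data
        _, counts = np.unique(srt[i], return_counts=True)
        t = counts.astype(float)
        tie[i] = np.sum(t**3 - t)
    var = n1 * n2 / 12.0 * ((n + 1) - tie / (n * (n - 1)))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.maximum(np.abs(u - mu) - 0.5, 0.0) / np.sqrt(var)
    p = np.where(var > 0, np.minimum(1.0, 2.0 * norm.sf(np.where(var > 0, z, 0.0))), 1.0)
    return u, p
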