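"""Nonparametric statistics for discounting cohorts.

Provides tie-aware ranking, the rank-sum (Wilcoxon/Mann-Whitney) Z test with
tie-corrected variance, Spearman rank correlation, and a permutation test
for the difference in Spearman correlation strength between two independent
groups.  The permutation test keeps each (x, y) pair intact and reshuffles
only the group labels, so it makes no distributional assumption about either
variable; a full-enumeration oracle is provided for small samples.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as _sps

__all__ = [
    "WilcoxonResult",
    "SpearmanResult",
    "PermCorrDiffResult",
    "rank_with_ties",
    "wilcoxon_rank_sum",
    "spearman",
    "corr_diff_statistic",
    "permutation_corr_diff",
    "exhaustive_corr_diff_null",
    "median_iqr",
]

MAX_EXHAUSTIVE_RELABELINGS = 10**6


@dataclass(frozen=True)
class WilcoxonResult:
    """Rank-sum test result.

    ``z`` follows the first-listed group: negative when group A's ranks sit
    below group B's.  ``mean_rank_diff`` is the mean rank of group A minus
    the mean rank of group B, a descriptive analogue of a rank-score mean
    difference.
    """

    z: float
    p_two_sided: float
    n_a: int
    n_b: int
    mean_rank_diff: float


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p_two_sided: float
    n: int
    defined: bool = True


@dataclass(frozen=True)
class PermCorrDiffResult:
    rho_a: float
    rho_b: float
    observed_diff: float
    p_two_sided: float
    n_resamples: int
    seed: int | None
    exhaustive: bool
    n_degenerate: int = 0


def rank_with_ties(values) -> np.ndarray:
    """Average ranks (1-based); tied values share the mean of their span."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot rank an empty sequence")
    return _sps.rankdata(arr, method="average")


def wilcoxon_rank_sum(group_a, group_b, continuity: bool = False) -> WilcoxonResult:
    """Two-sided rank-sum test with tie-corrected normal approximation.

    The statistic is W, the rank sum of ``group_a`` in the joint ranking.
    Under the null, E[W] = n_a (n+1) / 2 and

        Var[W] = n_a n_b / 12 * [ (n + 1) - sum(t^3 - t) / (n (n - 1)) ]

    where t runs over tie-group sizes.  ``continuity`` applies the 0.5
    continuity correction toward the mean (off by default).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    n_a, n_b = a.size, b.size
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs at least 2 observations")
    n = n_a + n_b
    ranks = rank_with_ties(np.concatenate([a, b]))
    w = float(ranks[:n_a].sum())
    expected = n_a * (n + 1) / 2.0
    _, tie_counts = np.unique(np.concatenate([a, b]), return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1))
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    mean_rank_diff = float(ranks[:n_a].mean() - ranks[n_a:].mean())
    if var <= 0:
        warnings.warn("all pooled values identical: rank-sum test is degenerate")
        return WilcoxonResult(0.0, 1.0, n_a, n_b, mean_rank_diff)
    delta = w - expected
    if continuity and delta != 0:
        delta -= 0.5 * math.copysign(1.0, delta)
    z = delta / math.sqrt(var)
    p = 2.0 * _sps.norm.sf(abs(z))
    return WilcoxonResult(float(z), min(1.0, float(p)), n_a, n_b, mean_rank_diff)


def spearman(x, y) -> SpearmanResult:
    """Spearman rank correlation with a t-approximation p value.

    rho is the product-moment correlation of tie-averaged ranks; the p value
    uses t = rho sqrt((n-2)/(1-rho^2)) on n-2 degrees of freedom.  If either
    vector has zero rank variance, rho is undefined and the result is
    flagged (``defined=False``, rho = nan, p = nan).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    rx = rank_with_ties(x)
    ry = rank_with_ties(y)
    sx = rx - rx.mean()
    sy = ry - ry.mean()
    den = math.sqrt(float(sx @ sx) * float(sy @ sy))
    if den == 0.0:
        return SpearmanResult(math.nan, math.nan, n, defined=False)
    rho = float(sx @ sy) / den
    rho = max(-1.0, min(1.0, rho))
    if abs(rho) == 1.0:
        p = 0.0
    else:
        t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        p = 2.0 * _sps.t.sf(abs(t), df=n - 2)
    return SpearmanResult(rho, min(1.0, float(p)), n)


def corr_diff_statistic(x_a, y_a, x_b, y_b) -> float:
    """Observed difference in Spearman correlation: rho_A - rho_B."""
    res_a = spearman(x_a, y_a)
    res_b = spearman(x_b, y_b)
    if not (res_a.defined and res_b.defined):
        raise ValueError("correlation undefined in one group (zero rank variance)")
    return res_a.rho - res_b.rho


def _rowwise_spearman(x2d: np.ndarray, y2d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Spearman rho per row of two 2-D arrays; flags degenerate rows."""
    rx = _sps.rankdata(x2d, method="average", axis=1)
    ry = _sps.rankdata(y2d, method="average", axis=1)
    rx -= rx.mean(axis=1, keepdims=True)
    ry -= ry.mean(axis=1, keepdims=True)
    vx = np.einsum("ij,ij->i", rx, rx)
    vy = np.einsum("ij,ij->i", ry, ry)
    den = np.sqrt(vx * vy)
    degenerate = den == 0.0
    num = np.einsum("ij,ij->i", rx, ry)
    rho = np.where(degenerate, 0.0, num / np.where(degenerate, 1.0, den))
    return rho, degenerate


def permutation_corr_diff(
    x_a,
    y_a,
    x_b,
    y_b,
    n_resamples: int = 100_000,
    seed: int | None = None,
    plus_one: bool = False,
    batch_size: int = 2_000,
) -> PermCorrDiffResult:
    """Permutation test for a difference in Spearman correlation strength.

    (x, y) pairs stay intact; group labels are reshuffled ``n_resamples``
    times, preserving the group sizes.  The two-sided p value is the
    proportion of resampled |rho_A - rho_B| that reach or exceed the
    observed |rho_A - rho_B|.  A resample in which either relabeled group
    has zero rank variance contributes a null difference of 0 and is
    counted in ``n_degenerate``.

    ``plus_one`` switches to the (count + 1) / (B + 1) estimator, which
    cannot return an exact zero; off by default, matching the plain
    proportion definition.  Identical seed and inputs give bit-identical
    results.
    """
    x_a = np.asarray(x_a, dtype=float)
    y_a = np.asarray(y_a, dtype=float)
    x_b = np.asarray(x_b, dtype=float)
    y_b = np.asarray(y_b, dtype=float)
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    observed = corr_diff_statistic(x_a, y_a, x_b, y_b)
    rho_a = spearman(x_a, y_a).rho
    rho_b = spearman(x_b, y_b).rho
    n_a = x_a.size
    x = np.concatenate([x_a, x_b])
    y = np.concatenate([y_a, y_b])
    # canonical pooled order: the resampling stream then depends only on the
    # pair multisets, not on input row order
    order = np.lexsort((y, x))
    x, y = x[order], y[order]
    n = x.size
    rng = np.random.default_rng(seed)
    exceed = 0
    n_degenerate = 0
    done = 0
    while done < n_resamples:
        b = min(batch_size, n_resamples - done)
        # each row of idx is an independent uniform permutation of 0..n-1
        idx = np.argsort(rng.random((b, n)), axis=1)
        ia, ib = idx[:, :n_a], idx[:, n_a:]
        rho_pa, deg_a = _rowwise_spearman(x[ia], y[ia])
        rho_pb, deg_b = _rowwise_spearman(x[ib], y[ib])
        deg = deg_a | deg_b
        diffs = np.where(deg, 0.0, rho_pa - rho_pb)
        n_degenerate += int(deg.sum())
        exceed += int(np.count_nonzero(np.abs(diffs) >= abs(observed) - 1e-12))
        done += b
    if plus_one:
        p = (exceed + 1) / (n_resamples + 1)
    else:
        p = exceed / n_resamples
    return PermCorrDiffResult(
        rho_a=rho_a,
        rho_b=rho_b,
        observed_diff=observed,
        p_two_sided=float(p),
        n_resamples=n_resamples,
        seed=seed,
        exhaustive=False,
        n_degenerate=n_degenerate,
    )


def exhaustive_corr_diff_null(x_a, y_a, x_b, y_b) -> PermCorrDiffResult:
    """Exact relabeling null for the correlation-difference test.

    Enumerates every assignment of the pooled pairs into groups of sizes
    (n_a, n_b) exactly once.  Only feasible while C(n, n_a) stays below
    ``MAX_EXHAUSTIVE_RELABELINGS``.
    """
    x_a = np.asarray(x_a, dtype=float)
    y_a = np.asarray(y_a, dtype=float)
    x_b = np.asarray(x_b, dtype=float)
    y_b = np.asarray(y_b, dtype=float)
    observed = corr_diff_statistic(x_a, y_a, x_b, y_b)
    n_a = x_a.size
    x = np.concatenate([x_a, x_b])
    y = np.concatenate([y_a, y_b])
    n = x.size
    total = math.comb(n, n_a)
    if total > MAX_EXHAUSTIVE_RELABELINGS:
        raise ValueError(
            f"C({n},{n_a}) = {total} relabelings exceed the exhaustive bound; "
            "use permutation_corr_diff"
        )
    all_idx = frozenset(range(n))
    exceed = 0
    n_degenerate = 0
    for combo in combinations(range(n), n_a):
        ia = np.fromiter(combo, dtype=int, count=n_a)
        ib = np.fromiter(sorted(all_idx - set(combo)), dtype=int, count=n - n_a)
        res_a = spearman(x[ia], y[ia])
        res_b = spearman(x[ib], y[ib])
        if not (res_a.defined and res_b.defined):
            n_degenerate += 1
            diff = 0.0
        else:
            diff = res_a.rho - res_b.rho
        if abs(diff) >= abs(observed) - 1e-12:
            exceed += 1
    return PermCorrDiffResult(
        rho_a=spearman(x_a, y_a).rho,
        rho_b=spearman(x_b, y_b).rho,
        observed_diff=observed,
        p_two_sided=exceed / total,
        n_resamples=total,
        seed=None,
        exhaustive=True,
        n_degenerate=n_degenerate,
    )


def median_iqr(values) -> tuple[float, float, float]:
    """(median, q1, q3) by linear interpolation between order statistics."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("median_iqr needs at least one value")
    med, q1, q3 = np.percentile(arr, [50, 25, 75])
    return float(med), float(q1), float(q3)
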