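"""Statistical primitives shared by the subtyping, clonality and EMT stages.

All tests are two-sided unless stated otherwise.  The Fisher exact test uses
the probability-mass definition of the two-sided p-value (sum of the
hypergeometric probabilities of every table with the observed margins whose
probability does not exceed that of the observed table), which is the
convention of mainstream implementations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

__all__ = [
    "ContingencyTable2x2",
    "fisher_exact_two_sided",
    "mann_whitney_u",
    "spearman_rho",
    "hypergeom_pmf",
]

#: combined sample size at or below which the Mann-Whitney test is exact
#: (when the pooled data carry no ties)
MANN_WHITNEY_EXACT_MAX_N = 20


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 table of non-negative counts; rows = groups, columns = outcomes."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if int(v) != v or v < 0:
                raise ValueError(f"counts must be non-negative integers, got {v!r}")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


def fisher_exact_two_sided(table: ContingencyTable2x2 | tuple | list | np.ndarray) -> float:
    """Two-sided Fisher exact p-value for a 2x2 count table.

    Parameters
    ----------
    table
        A :class:`ContingencyTable2x2`, or anything coercible to a 2x2
        integer array ``[[a, b], [c, d]]``.

    Raises
    ------
    ValueError
        If the table is all-zero (the test is undefined).
    """
    if not isinstance(table, ContingencyTable2x2):
        arr = np.asarray(table, dtype=np.int64)
        if arr.shape == (4,):
            arr = arr.reshape(2, 2)
        if arr.shape != (2, 2):
            raise ValueError(f"expected a 2x2 table, got shape {arr.shape}")
        table = ContingencyTable2x2(*arr.ravel().tolist())
    if table.total == 0:
        raise ValueError("Fisher exact test undefined for an all-zero table")
    res = _sps.fisher_exact(table.as_array(), alternative="two-sided")
    return float(min(1.0, res.pvalue))


def mann_whitney_u(x, y) -> dict:
    """Two-sided Mann-Whitney U test.

    The exact null distribution is used when ``len(x) + len(y) <= 20`` and
    the pooled sample has no ties; otherwise the normal approximation with
    tie correction (and continuity correction) is used.

    Returns
    -------
    dict with keys ``U`` (statistic for the first sample) and ``p_value``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("Mann-Whitney U requires at least one value per group")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= MANN_WHITNEY_EXACT_MAX_N and not has_ties) else "asymptotic"
    res = _sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return {"U": float(res.statistic), "p_value": float(min(1.0, res.pvalue))}


def spearman_rho(x, y, *, on_constant: str = "raise") -> float:
    """Spearman rank correlation (Pearson correlation of mid-ranks).

    Parameters
    ----------
    on_constant
        ``"raise"`` (default) raises :class:`ValueError` when either input
        is constant; ``"nan"`` returns ``float('nan')`` instead.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("Spearman correlation requires at least 3 pairs")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        if on_constant == "nan":
            return float("nan")
        raise ValueError("Spearman correlation undefined for constant input")
    rho = _sps.spearmanr(x, y).statistic
    return float(rho)


def spearman_test(x, y) -> dict:
    """Spearman rho together with its two-sided p-value."""
    rho = spearman_rho(x, y)
    res = _sps.spearmanr(np.asarray(x, float), np.asarray(y, float))
    return {"rho": rho, "p_value": float(res.pvalue)}


def hypergeom_pmf(k: int, N: int, K: int, n: int) -> float:
    """P(X = k) for X ~ Hypergeometric(N population, K successes, n draws)."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("invalid hypergeometric parameters")
    if k < max(0, n + K - N) or k > min(n, K):
        return 0.0
    return math.exp(
        _log_comb(K, k) + _log_comb(N - K, n - k) - _log_comb(N, n)
    )


def _log_comb(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)
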