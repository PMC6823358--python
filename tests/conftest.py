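"""Shared fixtures and independent brute-force oracles.

The oracles here recompute expected values from first principles
(exact hypergeometric enumeration, rank-split enumeration, exhaustive
rooted-tree parsimony) and are deliberately kept independent of the
implementation code paths they check.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest

from cstyper.simulate import GeneratorConfig, generate_cohort, panel_loci


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exact hypergeometric enumeration (rationals)."""
    r1, r2, c1 = a + b, c + d, a + c
    N = r1 + r2
    denom = math.comb(N, c1)

    def pr(k: int) -> Fraction:
        return Fraction(math.comb(r1, k) * math.comb(r2, c1 - k), denom)

    p_obs = pr(a)
    cutoff = p_obs * (Fraction(10**7 + 1, 10**7))  # relative tolerance 1e-7
    total = Fraction(0)
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = pr(k)
        if p <= cutoff:
            total += p
    return float(min(total, Fraction(1)))


def mann_whitney_exact_oracle(x, y) -> float:
    """Exact two-sided p by enumerating all rank assignments (no ties)."""
    pooled = sorted(x) + sorted(y)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    n_x = len(x)
    ranks = {v: i + 1 for i, v in enumerate(sorted(pooled))}
    u_obs = sum(ranks[v] for v in x) - n_x * (n_x + 1) / 2
    mu = n_x * len(y) / 2
    us = []
    for comb in itertools.combinations(range(1, len(pooled) + 1), n_x):
        us.append(sum(comb) - n_x * (n_x + 1) / 2)
    extreme = sum(1 for u in us if abs(u - mu) >= abs(u_obs - mu) - 1e-12)
    return extreme / len(us)


def parsimony_oracle(matrix) -> int:
    """Minimum parsimony length over all trees, by exhaustive enumeration of
    rooted binary trees on the regions (root = all-absent germline)."""
    M = np.asarray(matrix, dtype=int)
    n, n_chars = M.shape

    def bipartitions(S):
        first, rest = S[0], S[1:]
        for r in range(len(rest)):
            for comb in itertools.combinations(rest, r):
                A = (first,) + comb
                B = tuple(v for v in rest if v not in comb)
                if B:
                    yield A, B

    def gen(S):
        if len(S) == 1:
            yield S[0]
            return
        for A, B in bipartitions(S):
            for t1 in gen(A):
                for t2 in gen(B):
                    yield (t1, t2)

    best = None
    for t in gen(tuple(range(n))):
        total = 0
        for j in range(n_chars):
            changes = 0

            def fitch(node):
                nonlocal changes
                if isinstance(node, (int, np.integer)):
                    return {int(M[node][j])}
                s1, s2 = fitch(node[0]), fitch(node[1])
                inter = s1 & s2
                if inter:
                    return inter
                changes += 1
                return s1 | s2

            root_set = fitch(t)
            if 0 not in root_set:
                changes += 1
            total += changes
        if best is None or total < best:
            best = total
    return best


@pytest.fixture(scope="session")
def oracle():
    class Oracles:
        fisher = staticmethod(fisher_oracle)
        mann_whitney = staticmethod(mann_whitney_exact_oracle)
        parsimony = staticmethod(parsimony_oracle)

    return Oracles


# ---------------------------------------------------------------------------
# cohort fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def loci():
    return panel_loci()


@pytest.fixture(scope="session")
def small_cohort():
    """A small but complete cohort with every subtype represented."""
    cfg = GeneratorConfig(
        n_samples=28,
        subtype_counts={"POLE": 3, "MSI": 6, "CNH": 15, "CNL": 4},
    )
    profiles, truth = generate_cohort(cfg, seed=11)
    return profiles, truth, cfg


@pytest.fixture(scope="session")
def default_cohort():
    profiles, truth = generate_cohort(seed=7)
    return profiles, truth
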