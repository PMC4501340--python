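"""Statistical kernel: Yates-corrected G-test on 2x2 tables, chi-square tail,
Benjamini-Hochberg FDR and the hypergeometric over-representation tail.

The G-test is the likelihood-ratio counterpart of Pearson's chi-square,

    G = 2 * sum_ij O'_ij * ln(O'_ij / E_ij),

computed here on a 2x2 contingency table whose first row is the pooled
spectral count of a target protein in two groups and whose second row is the
count of all other proteins. The continuity correction shifts each observed
cell 0.5 toward its expected value (capped so it never crosses it), which
keeps the test usable on small counts including zero; G is referred to the
chi-square distribution with one degree of freedom.
"""

from __future__ import annotations

from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GTestResult",
    "g_test_yates",
    "g_test_uncorrected",
    "chisq_tail_df1",
    "bh_fdr",
    "hypergeom_tail",
]


class GTestResult(NamedTuple):
    g_stat: float
    p_value: float
    degenerate: bool = False


def _as_2x2(table) -> np.ndarray:
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {arr.shape}")
    if (arr < 0).any():
        raise ValueError("contingency table entries must be >= 0")
    if arr.sum() <= 0:
        raise ValueError("contingency table grand total must be > 0")
    return arr


def g_test_yates(table) -> GTestResult:
    """Yates-corrected G-test of independence on a 2x2 table.

    Returns the G statistic and the upper-tail chi-square (df=1) p-value.
    A table with an empty row or column carries no information about
    association; it is flagged ``degenerate`` and returns (G=0, p=1) instead
    of raising, so absent proteins do not abort a batch comparison.
    """
    obs = _as_2x2(table)
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        return GTestResult(0.0, 1.0, degenerate=True)
    expected = np.outer(rows, cols) / obs.sum()
    shift = np.sign(expected - obs) * np.minimum(0.5, np.abs(expected - obs))
    adj = obs + shift
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(adj > 0, adj * np.log(adj / expected), 0.0)
    g = max(2.0 * float(terms.sum()), 0.0)
    return GTestResult(g, chisq_tail_df1(g), degenerate=False)


def g_test_uncorrected(table) -> GTestResult:
    """Plain (no continuity correction) G-test; used for comparison only."""
    obs = _as_2x2(table)
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        return GTestResult(0.0, 1.0, degenerate=True)
    expected = np.outer(rows, cols) / obs.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(obs > 0, obs * np.log(obs / expected), 0.0)
    g = max(2.0 * float(terms.sum()), 0.0)
    return GTestResult(g, chisq_tail_df1(g), degenerate=False)


def chisq_tail_df1(x: float) -> float:
    """Upper-tail probability of the chi-square distribution with 1 df."""
    if x < 0:
        raise ValueError(f"chi-square statistic must be >= 0, got {x}")
    return float(sps.chi2.sf(x, df=1))


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order.

    q_i = min_{j: p_(j) >= p_(i)} (m * p_(j) / j), clipped at 1.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("bh_fdr requires at least one p-value")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def hypergeom_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) drawing n items from a universe of N containing K successes.

    This is the standard over-representation p-value: the chance that a
    random selection of ``n`` genes from the ``N``-gene universe overlaps a
    ``K``-gene set in at least ``k`` members.
    """
    if not (0 <= k <= min(n, K) <= N) or n > N:
        raise ValueError(
            f"inconsistent hypergeometric arguments: k={k}, n={n}, K={K}, N={N}"
        )
    if k == 0:
        return 1.0
    return float(sps.hypergeom.sf(k - 1, N, K, n))
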