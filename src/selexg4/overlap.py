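"""Hypergeometric gene-list overlap with representation factor.

Given two gene lists drawn from a universe of N genes, the expected
overlap under independence is n1*n2/N; the representation factor is the
observed overlap divided by that expectation, and significance is the
upper hypergeometric tail P(X >= k).  The universe size must be given
explicitly — it dominates the p-value and has no safe default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy.special import gammaln, logsumexp

__all__ = ["OverlapResult", "overlap_test", "hypergeom_sf", "read_gene_list"]


@dataclass(frozen=True)
class OverlapResult:
    n1: int
    n2: int
    k: int
    universe_n: int
    expected: float
    representation_factor: float
    pvalue_ge: float

    def as_dict(self) -> dict:
        return {
            "n1": self.n1,
            "n2": self.n2,
            "overlap": self.k,
            "universe_n": self.universe_n,
            "expected_overlap": self.expected,
            "representation_factor": self.representation_factor,
            "pvalue_ge": self.pvalue_ge,
        }


def _log_comb(n: int, k) -> np.ndarray:
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_sf(k: int, N: int, K: int, n: int) -> float:
    """Upper tail P(X >= k) for X ~ Hypergeometric(N, K, n), in log space.

    X counts successes in a draw of n from a universe of N containing K
    successes.  Summation of log-binomial terms via logsumexp keeps the
    tail accurate far below float underflow of individual terms.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"invalid hypergeometric parameters N={N}, K={K}, n={n}")
    hi = min(K, n)
    lo = max(0, n - (N - K))
    if k > hi:
        return 0.0
    if k <= lo:
        return 1.0
    i = np.arange(k, hi + 1)
    log_terms = _log_comb(K, i) + _log_comb(N - K, n - i) - _log_comb(N, n)
    return float(min(1.0, np.exp(logsumexp(log_terms))))


def _normalize(genes: Iterable[str]) -> set[str]:
    return {g.strip().upper() for g in genes if g and g.strip()}


def overlap_test(list1: Iterable[str], list2: Iterable[str], universe_n: int) -> OverlapResult:
    """Overlap size, representation factor and hypergeometric P(X >= k).

    Gene identifiers are case-normalized and de-duplicated before the
    set operations.
    """
    s1, s2 = _normalize(list1), _normalize(list2)
    union = len(s1 | s2)
    if universe_n < union:
        raise ValueError(f"universe_n={universe_n} smaller than the union ({union})")
    n1, n2, k = len(s1), len(s2), len(s1 & s2)
    expected = n1 * n2 / universe_n
    rf = k / expected if expected > 0 else float("nan")
    p = hypergeom_sf(k, universe_n, n1, n2)
    return OverlapResult(n1, n2, k, universe_n, expected, rf, p)


def read_gene_list(handle) -> list[str]:
    """Newline-delimited gene identifiers; blank lines skipped."""
    return [line.strip() for line in handle if line.strip()]
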