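"""Competition-assay retention statistics.

Equimolar mixtures of aptamers are immunoprecipitated under different
conditions; deep sequencing of the retained material yields per-aptamer
counts.  The core statistic is the fold enrichment (FE): per replicate,
the ratio of a target aptamer's retained count to the scrambled control
(scr50).  Conditions are compared with a two-tailed Mann-Whitney U test
(exact enumeration for small samples) or a two-tailed Student's t-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from itertools import combinations
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np
from scipy import stats

__all__ = [
    "CompetitionTable",
    "FEResult",
    "TestKind",
    "retention_frequencies",
    "fold_enrichment",
    "mann_whitney_exact",
    "compare_fe",
    "condition_fe_table",
    "read_competition_tsv",
    "write_fe_tsv",
]

CONTROL_ID = "scr50"
EXACT_MW_MAX_N = 12  # exact enumeration up to this pooled sample size


class TestKind(str, Enum):
    MANN_WHITNEY_TWO_TAILED = "mann_whitney_two_tailed"
    T_TEST_TWO_TAILED = "t_test_two_tailed"


@dataclass(frozen=True)
class CompetitionTable:
    """Retained-read counts of each named aptamer for one replicate."""

    condition: str
    replicate: int
    counts: dict[str, int]

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("counts must be non-negative")
        if sum(self.counts.values()) <= 0:
            raise ValueError(f"{self.condition} rep {self.replicate}: all-zero table")


@dataclass(frozen=True)
class FEResult:
    aptamer_id: str
    fe_per_replicate: tuple[float, ...]
    mean_fe: float
    pvalue: float
    test: TestKind


def retention_frequencies(table: CompetitionTable) -> dict[str, float]:
    """Relative retention frequency per aptamer; sums to 1."""
    total = sum(table.counts.values())
    return {apt: c / total for apt, c in table.counts.items()}


def fold_enrichment(
    table: CompetitionTable,
    target: str,
    control: str = CONTROL_ID,
    pseudocount: float = 0.0,
) -> float:
    """FE = count(target) / count(control) within one replicate.

    Scale-invariant by construction.  A zero control count is an error
    unless a pseudocount (e.g. 0.5 added to every aptamer) is supplied.
    """
    num = table.counts.get(target, 0) + pseudocount
    den = table.counts.get(control, 0) + pseudocount
    if den == 0:
        raise ZeroDivisionError(
            f"{table.condition} rep {table.replicate}: control {control!r} has zero "
            "count; pass pseudocount=0.5 to compute a finite FE"
        )
    return num / den


def _u_statistic(x: Sequence[float], y: Sequence[float]) -> float:
    """Mann-Whitney U of x over y with midrank (0.5) handling of ties."""
    u = 0.0
    for xi in x:
        for yi in y:
            if xi > yi:
                u += 1.0
            elif xi == yi:
                u += 0.5
    return u


def mann_whitney_exact(x: Sequence[float], y: Sequence[float]) -> float:
    """Exact two-tailed Mann-Whitney p by enumeration of all labelings.

    Every C(n1+n2, n1) relabeling of the pooled observations is scored;
    the p-value is the fraction whose U deviates from its null mean
    n1*n2/2 at least as much as the observed U.  Ties contribute
    midranks, so the enumeration is valid with ties.
    """
    n1, n2 = len(x), len(y)
    pooled = list(x) + list(y)
    u_obs = _u_statistic(x, y)
    center = n1 * n2 / 2.0
    d_obs = abs(u_obs - center)
    hits = 0
    total = 0
    idx = range(n1 + n2)
    for group1 in combinations(idx, n1):
        g1 = set(group1)
        xs = [pooled[i] for i in group1]
        ys = [pooled[i] for i in idx if i not in g1]
        if abs(_u_statistic(xs, ys) - center) >= d_obs - 1e-12:
            hits += 1
        total += 1
    return hits / total


def compare_fe(
    control_fes: Sequence[float],
    treated_fes: Sequence[float],
    test: TestKind = TestKind.MANN_WHITNEY_TWO_TAILED,
) -> float:
    """Two-tailed p-value comparing FE values between two conditions.

    Mann-Whitney uses exact enumeration when n1 + n2 <= 12 (replicate
    counts in competition assays are tiny) and the normal approximation
    with tie correction otherwise; the t-test assumes >= 2 per group.
    """
    x = list(control_fes)
    y = list(treated_fes)
    if not x or not y:
        raise ValueError("both groups must be non-empty")
    if test is TestKind.T_TEST_TWO_TAILED:
        if len(x) < 2 or len(y) < 2:
            raise ValueError("t-test requires at least 2 replicates per group")
        return float(stats.ttest_ind(x, y).pvalue)
    if len(x) + len(y) <= EXACT_MW_MAX_N:
        return mann_whitney_exact(x, y)
    return float(
        stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
    )


def condition_fe_table(
    tables: Iterable[CompetitionTable],
    targets: Sequence[str],
    control: str = CONTROL_ID,
    pseudocount: float = 0.0,
) -> dict[str, dict[str, list[float]]]:
    """Per condition, per target aptamer, the FE values across replicates.

    When a condition has a single replicate the per-aptamer ratios can
    be pooled into one sample for testing (``pooled`` key), mirroring
    the practice of comparing the means over all computed ratios.
    """
    out: dict[str, dict[str, list[float]]] = {}
    for t in sorted(tables, key=lambda t: (t.condition, t.replicate)):
        cond = out.setdefault(t.condition, {a: [] for a in targets})
        for target in targets:
            cond[target].append(fold_enrichment(t, target, control, pseudocount))
    for cond in out.values():
        cond["pooled"] = [fe for a in targets for fe in cond[a]]
    return out


def read_competition_tsv(handle: TextIO) -> list[CompetitionTable]:
    """Read (condition, replicate, aptamer_id, count) rows into tables."""
    acc: dict[tuple[str, int], dict[str, int]] = {}
    header = handle.readline().strip().split("\t")
    expected = ["condition", "replicate", "aptamer_id", "count"]
    if header != expected:
        raise ValueError(f"expected header {expected}, got {header}")
    for line in handle:
        if not line.strip():
            continue
        cond, rep, apt, count = line.rstrip("\n").split("\t")
        acc.setdefault((cond, int(rep)), {})[apt] = int(count)
    return [
        CompetitionTable(cond, rep, counts)
        for (cond, rep), counts in sorted(acc.items())
    ]


def write_fe_tsv(results: Sequence[FEResult], handle: TextIO) -> None:
    handle.write("aptamer_id\tmean_fe\tpvalue\ttest\tfe_per_replicate\n")
    for r in results:
        fes = ",".join(f"{v:.6g}" for v in r.fe_per_replicate)
        handle.write(f"{r.aptamer_id}\t{r.mean_fe:.6g}\t{r.pvalue:.6g}\t{r.test.value}\t{fes}\n")
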