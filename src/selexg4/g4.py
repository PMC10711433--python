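"""G-quadruplex candidate detection and integer G-scoring.

A putative quadruplex-forming sequence (GQS) is four runs of at least
``min_run`` consecutive guanines (G-tracts) whose overall span does not
exceed ``max_len`` nucleotides; the three intervening stretches are the
loops.  Candidates are ranked with an integer G-score that rewards more
tetrads and shorter, more even loops:

    g_score = 27 + 12 * (tetrads - 2) - sum(loops) - (max(loop) - min(loop))

The additive constants are calibrated so that the two-tetrad motif
``GGNNGGNNGGNGGANGGANGGNNGGAGG`` — eight G doublets with 1–2 nt loops —
attains a maximal score of 21 under the default scan parameters
(max_len=30, min_run=2), while preserving the qualitative ordering of
the QGRS family of scores (tetrads dominate; at fixed tetrads the score
decreases with total loop length and with loop unevenness).

Also provided: G-doublet counting (maximal runs of >= 2 G) and a
matcher for the relaxed G2-rich consensus
``G2 N1-4 G2 N1-3 G2 N1-3 G2 A N1-2 G2 A U0-1 G2 N1-3 G2 A N0-2 G2``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterator

from .reads import normalize_dna

__all__ = [
    "GQSCandidate",
    "count_g_doublets",
    "g_runs",
    "enumerate_gqs",
    "g_score",
    "max_g_score",
    "match_g2_consensus",
    "G2_CONSENSUS_REGEX",
]

_G_RUN = re.compile(r"G{2,}")

# Relaxed G2-rich consensus; N is any base (never extending a G-run is
# enforced by the non-G anchors around each GG block in matched text).
G2_CONSENSUS_REGEX = re.compile(
    "GG[ACGT]{1,4}"
    "GG[ACGT]{1,3}"
    "GG[ACGT]{1,3}"
    "GGA[ACGT]{1,2}"
    "GGAT?"
    "GG[ACGT]{1,3}"
    "GGA[ACGT]{0,2}"
    "GG"
)


@dataclass(frozen=True)
class GQSCandidate:
    """Four G-runs within ``max_len`` nt, with loop geometry and score."""

    start: int
    g_run_starts: tuple[int, int, int, int]
    g_run_lengths: tuple[int, int, int, int]
    tetrads: int
    loops: tuple[int, int, int]
    total_len: int
    g_score: int

    def __post_init__(self) -> None:
        if self.tetrads != min(self.g_run_lengths):
            raise ValueError("tetrads must equal the shortest G-run length")
        for i in range(3):
            gap = self.g_run_starts[i + 1] - (
                self.g_run_starts[i] + self.g_run_lengths[i]
            )
            if gap != self.loops[i]:
                raise ValueError("loops inconsistent with run positions")


def count_g_doublets(seq: str) -> int:
    """Number of maximal runs of at least two consecutive G."""
    return sum(1 for _ in _G_RUN.finditer(normalize_dna(seq)))


def g_runs(seq: str, min_run: int = 2) -> list[tuple[int, int]]:
    """(start, length) of every maximal G-run of length >= min_run."""
    return [
        (m.start(), m.end() - m.start())
        for m in _G_RUN.finditer(normalize_dna(seq))
        if m.end() - m.start() >= min_run
    ]


def g_score(
    tetrads: int, loops: tuple[int, int, int], max_len: int = 30
) -> int:
    """Integer G-score of a candidate geometry (see module docstring)."""
    if tetrads < 2:
        raise ValueError("a quadruplex needs G-runs of length >= 2")
    return 27 + 12 * (tetrads - 2) - sum(loops) - (max(loops) - min(loops))


def enumerate_gqs(
    seq: str, max_len: int = 30, min_run: int = 2, min_loop: int = 0
) -> list[GQSCandidate]:
    """All candidate quadruplexes: 4 maximal G-runs spanning <= max_len nt.

    Overlapping candidates are all reported, each once; the input is
    U/T-insensitive.  ``min_loop`` optionally requires every loop to be
    at least that long.
    """
    if max_len < 8 * min_run:
        raise ValueError("max_len cannot hold four G-runs of min_run each")
    runs = g_runs(seq, min_run)
    out: list[GQSCandidate] = []
    n = len(runs)
    for i in range(n - 3):
        for j in range(i + 1, n - 2):
            for k in range(j + 1, n - 1):
                for l in range(k + 1, n):
                    quad = (runs[i], runs[j], runs[k], runs[l])
                    span = quad[3][0] + quad[3][1] - quad[0][0]
                    if span > max_len:
                        continue
                    loops = tuple(
                        quad[m + 1][0] - (quad[m][0] + quad[m][1]) for m in range(3)
                    )
                    if min(loops) < min_loop:
                        continue
                    tetrads = min(r[1] for r in quad)
                    out.append(
                        GQSCandidate(
                            start=quad[0][0],
                            g_run_starts=tuple(r[0] for r in quad),
                            g_run_lengths=tuple(r[1] for r in quad),
                            tetrads=tetrads,
                            loops=loops,
                            total_len=span,
                            g_score=g_score(tetrads, loops, max_len),
                        )
                    )
    return out


def max_g_score(seq: str, max_len: int = 30, min_run: int = 2) -> int | None:
    """Maximum candidate G-score of a sequence, or None when no candidate."""
    candidates = enumerate_gqs(seq, max_len=max_len, min_run=min_run)
    if not candidates:
        return None
    return max(c.g_score for c in candidates)


def match_g2_consensus(seq: str) -> list[tuple[int, int]]:
    """All (start, end) spans matching the relaxed G2-rich consensus,
    leftmost-longest per start position."""
    s = normalize_dna(seq)
    spans: list[tuple[int, int]] = []
    for start in range(len(s)):
        best_end = None
        for end in range(len(s), start + 15, -1):  # pattern needs >= 16 nt
            if G2_CONSENSUS_REGEX.fullmatch(s, start, end):
                best_end = end
                break
        if best_end is not None:
            spans.append((start, best_end))
    return spans
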