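"""Per-round counting, detection thresholds, composition and k-mer logos.

Round-over-round enrichment is tracked on the variable regions that
survive quality filtering and flank extraction.  Detection uses a strict
frequency threshold (e.g. 5e-5, i.e. more than 50 copies per million
reads) in at least one round.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np

__all__ = [
    "RoundCountTable",
    "SequenceSeries",
    "PWM",
    "count_round",
    "detected_sequences",
    "pool_fraction",
    "composition_by_round",
    "kmer_frequencies",
    "kmer_logo",
    "align_offset",
    "weighted_pwm",
    "write_counts_tsv",
    "write_meme",
]

ALPHABET = "ACGT"

# Detection thresholds, stored as fractions: >0.003% for the DNA screen,
# >0.005% (50 copies per million) for the RNA screen.
MIN_FREQ_DNA = 3e-5
MIN_FREQ_RNA = 5e-5


@dataclass(frozen=True)
class RoundCountTable:
    """Multiset tally of unique variable regions for one selection round."""

    round_index: int
    counts: dict[str, int]
    total_reads: int

    def __post_init__(self) -> None:
        if self.total_reads != sum(self.counts.values()):
            raise ValueError("total_reads must equal the sum of counts")

    def frequency(self, seq: str) -> float:
        return self.counts.get(seq, 0) / self.total_reads

    def frequencies(self) -> dict[str, float]:
        t = self.total_reads
        return {s: c / t for s, c in self.counts.items()}


@dataclass(frozen=True)
class SequenceSeries:
    """Frequency trajectory of one sequence across rounds (0 where absent)."""

    sequence: str
    freq_by_round: dict[int, float]

    def max_freq(self) -> float:
        return max(self.freq_by_round.values())


@dataclass(frozen=True)
class PWM:
    """Position weight matrix over A/C/G/T; every column sums to 1."""

    matrix: np.ndarray  # shape (width, 4), rows = positions

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4:
            raise ValueError("PWM matrix must have shape (width, 4)")
        if (m < 0).any() or not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM columns must be non-negative and sum to 1")
        object.__setattr__(self, "matrix", m)

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    def column(self, i: int) -> dict[str, float]:
        return dict(zip(ALPHABET, self.matrix[i]))

    def consensus(self) -> str:
        return "".join(ALPHABET[j] for j in self.matrix.argmax(axis=1))


def count_round(regions: Iterable[str], round_index: int) -> RoundCountTable:
    """Exact multiset tally of variable regions for one round."""
    counts = Counter(regions)
    if not counts:
        raise ValueError(f"round {round_index}: no surviving reads to count")
    return RoundCountTable(round_index, dict(counts), sum(counts.values()))


def detected_sequences(
    tables: Sequence[RoundCountTable], min_freq: float
) -> list[SequenceSeries]:
    """Sequences whose frequency strictly exceeds ``min_freq`` in >= 1 round.

    Each detected sequence carries its full frequency series over all
    rounds, with 0 where it was absent.  The result is sorted by
    last-round frequency descending (ties lexicographic) and does not
    depend on input read order.
    """
    if not 0 < min_freq < 1:
        raise ValueError("min_freq must lie in (0, 1)")
    detected: set[str] = set()
    for table in tables:
        t = table.total_reads
        detected.update(s for s, c in table.counts.items() if c / t > min_freq)
    rounds = [t.round_index for t in tables]
    series = [
        SequenceSeries(s, {r: t.frequency(s) for r, t in zip(rounds, tables)})
        for s in detected
    ]
    last = rounds[-1] if rounds else 0
    series.sort(key=lambda x: (-x.freq_by_round.get(last, 0.0), x.sequence))
    return series


def pool_fraction(
    kept: Sequence[SequenceSeries], tables: Sequence[RoundCountTable]
) -> dict[int, float]:
    """Per round, the summed frequency of the kept sequences."""
    out: dict[int, float] = {}
    for table in tables:
        r = table.round_index
        out[r] = float(sum(s.freq_by_round.get(r, 0.0) for s in kept))
    return out


def composition_by_round(table: RoundCountTable) -> dict[str, float]:
    """Count-weighted average per-position base frequencies for a round.

    All sequences must share one length; the four values sum to 1.  For
    an unbiased random library this is ~25% per base at round 0.
    """
    lengths = {len(s) for s in table.counts}
    if len(lengths) != 1:
        raise ValueError(f"mixed sequence lengths in round {table.round_index}: {sorted(lengths)}")
    width = lengths.pop()
    tallies = np.zeros((width, 4))
    index = {b: i for i, b in enumerate(ALPHABET)}
    for seq, count in table.counts.items():
        for pos, base in enumerate(seq):
            tallies[pos, index[base]] += count
    per_pos = tallies / tallies.sum(axis=1, keepdims=True)
    mean = per_pos.mean(axis=0)
    return dict(zip(ALPHABET, mean.tolist()))


def kmer_frequencies(table: RoundCountTable, k: int = 8) -> dict[str, float]:
    """Count-weighted sliding-window k-mer frequencies, normalized to sum 1."""
    tally: Counter[str] = Counter()
    for seq, count in table.counts.items():
        if k > len(seq):
            raise ValueError(f"k={k} exceeds sequence length {len(seq)}")
        for i in range(len(seq) - k + 1):
            tally[seq[i : i + k]] += count
    total = sum(tally.values())
    return {kmer: c / total for kmer, c in tally.items()}


def align_offset(ref: str, other: str, max_shift: int = 3) -> int:
    """Ungapped offset of ``other`` against ``ref`` maximizing identity.

    Offsets are searched in -max_shift..+max_shift; ties prefer the
    offset closest to zero (and zero itself when tied).
    """
    best = (-1, 0, 0)  # (identity, -abs(offset) preference via sort key)
    candidates = []
    for off in range(-max_shift, max_shift + 1):
        ident = 0
        for i, base in enumerate(ref):
            j = i - off
            if 0 <= j < len(other) and other[j] == base:
                ident += 1
        candidates.append((ident, off))
    candidates.sort(key=lambda c: (-c[0], abs(c[1]), c[1]))
    return candidates[0][1]


def weighted_pwm(
    aligned: Sequence[tuple[str, int, float]], width: int
) -> PWM:
    """Build a PWM from (sequence, offset, weight) triples over ``width``
    reference positions; columns are renormalized over covering sequences."""
    index = {b: i for i, b in enumerate(ALPHABET)}
    m = np.zeros((width, 4))
    for seq, off, w in aligned:
        for i in range(width):
            j = i - off
            if 0 <= j < len(seq):
                m[i, index[seq[j]]] += w
    sums = m.sum(axis=1, keepdims=True)
    if (sums == 0).any():
        raise ValueError("uncovered PWM column; shifts exceed sequence span")
    return PWM(m / sums)


def kmer_logo(kmer_freqs: Mapping[str, float], top_n: int = 20) -> PWM:
    """Frequency-weighted PWM of the ``top_n`` most frequent k-mers,
    ungapped-aligned (offset -3..+3) to the single most frequent one."""
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    ranked = sorted(kmer_freqs.items(), key=lambda kv: (-kv[1], kv[0]))[:top_n]
    ref = ranked[0][0]
    aligned = [(kmer, align_offset(ref, kmer), w) for kmer, w in ranked]
    return weighted_pwm(aligned, len(ref))


def write_counts_tsv(table: RoundCountTable, handle: TextIO) -> None:
    handle.write("sequence\tcount\tfrequency\tround\n")
    ranked = sorted(table.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    for seq, count in ranked:
        handle.write(f"{seq}\t{count}\t{count / table.total_reads:.6g}\t{table.round_index}\n")


def write_meme(pwm: PWM, handle: TextIO, name: str = "motif") -> None:
    """Write a PWM in MEME minimal motif format."""
    handle.write("MEME version 4\n\nALPHABET= ACGT\n\n")
    handle.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
    handle.write(f"MOTIF {name}\n")
    handle.write(f"letter-probability matrix: alength= 4 w= {pwm.width}\n")
    for row in pwm.matrix:
        handle.write(" ".join(f"{v:.6f}" for v in row) + "\n")
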