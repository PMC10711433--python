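"""FASTQ parsing, Phred quality filtering and variable-region recovery.

SELEX libraries are built as ``flank5 + N_k + flank3``: a random core of
fixed length between two constant primer-derived flanks.  This module
recovers the variable region from sequencing reads and applies an
all-bases quality filter: a read is kept only if every base has a Phred
quality of at least ``qmin`` (default 30, i.e. a per-base error
probability below 1e-3).
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, TextIO

from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "QualityRead",
    "LibraryDesign",
    "Chemistry",
    "RejectionReason",
    "ExtractionReport",
    "FastqParseError",
    "parse_fastq",
    "open_fastq",
    "phred_error_prob",
    "quality_pass",
    "extract_variable_region",
    "normalize_dna",
    "to_chemistry",
    "write_count_fasta",
]

PHRED_OFFSET = 33
_MAX_PHRED = 93

_DNA_TRANS = str.maketrans("acgtun", "ACGTTN")


def normalize_dna(seq: str) -> str:
    """Uppercase and map U -> T so RNA and DNA inputs share one alphabet."""
    return seq.upper().replace("U", "T").translate(_DNA_TRANS)


class Chemistry(str, Enum):
    DNA = "DNA"
    RNA = "RNA"


def to_chemistry(seq: str, chemistry: Chemistry) -> str:
    """Print an internally DNA-normalized sequence in its native alphabet."""
    return seq.replace("T", "U") if chemistry is Chemistry.RNA else seq


@dataclass(frozen=True)
class QualityRead:
    """A single sequencing read with per-base Phred qualities."""

    read_id: str
    bases: str
    quals: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.quals) != len(self.bases):
            raise ValueError(
                f"read {self.read_id!r}: {len(self.bases)} bases but "
                f"{len(self.quals)} quality scores"
            )
        for q in self.quals:
            if not 0 <= q <= _MAX_PHRED:
                raise ValueError(f"read {self.read_id!r}: Phred score {q} out of range")


@dataclass(frozen=True)
class LibraryDesign:
    """Fixed-flank library layout: ``flank5 + N_var_len + flank3``."""

    flank5: str
    flank3: str
    var_len: int
    chemistry: Chemistry = Chemistry.DNA

    def __post_init__(self) -> None:
        if not self.flank5 or not self.flank3:
            raise ValueError("flanks must be non-empty")
        if self.var_len <= 0:
            raise ValueError("var_len must be positive")
        object.__setattr__(self, "flank5", normalize_dna(self.flank5))
        object.__setattr__(self, "flank3", normalize_dna(self.flank3))

    @property
    def read_length(self) -> int:
        return len(self.flank5) + self.var_len + len(self.flank3)


class RejectionReason(str, Enum):
    FLANK5_MISSING = "flank5_missing"
    FLANK3_MISSING = "flank3_missing"
    BAD_LENGTH = "bad_length"
    LOW_QUALITY = "low_quality"


@dataclass
class ExtractionReport:
    """Running tally of read fates; raw == passed + sum(rejected)."""

    raw: int = 0
    passed: int = 0
    rejected: dict[str, int] = field(default_factory=dict)

    def reject(self, reason: RejectionReason) -> None:
        self.raw += 1
        self.rejected[reason.value] = self.rejected.get(reason.value, 0) + 1

    def accept(self) -> None:
        self.raw += 1
        self.passed += 1

    def as_dict(self) -> dict:
        return {"raw": self.raw, "passed": self.passed, "rejected": dict(self.rejected)}


class FastqParseError(ValueError):
    """Malformed FASTQ record; carries the approximate 1-based line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


def parse_fastq(stream: TextIO, offset: int = PHRED_OFFSET) -> Iterator[QualityRead]:
    """Yield :class:`QualityRead` per 4-line FASTQ record, order preserved.

    Malformed records (missing ``+`` separator, sequence/quality length
    mismatch, truncated file) raise :class:`FastqParseError` naming the
    line where the offending record starts.
    """
    n_records = 0
    it = FastqGeneralIterator(stream)
    while True:
        line = 4 * n_records + 1
        try:
            title, seq, qual = next(it)
        except StopIteration:
            return
        except ValueError as exc:
            raise FastqParseError(str(exc), line) from exc
        if len(seq) != len(qual):
            raise FastqParseError(
                f"sequence length {len(seq)} != quality length {len(qual)}", line
            )
        quals = tuple(ord(c) - offset for c in qual)
        try:
            yield QualityRead(title.split()[0] if title else "", seq, quals)
        except ValueError as exc:
            raise FastqParseError(str(exc), line) from exc
        n_records += 1


def open_fastq(path) -> TextIO:
    """Open a FASTQ file, transparently gunzipping ``.gz`` paths."""
    path = str(path)
    if path.endswith(".gz"):
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path)


def phred_error_prob(q: int) -> float:
    """Per-base error probability P = 10^(-Q/10)."""
    if q < 0:
        raise ValueError(f"Phred score must be non-negative, got {q}")
    return 10.0 ** (-q / 10.0)


def quality_pass(read: QualityRead, qmin: int = 30) -> bool:
    """True iff every base has quality >= qmin (vacuously true when empty)."""
    return all(q >= qmin for q in read.quals)


def _mismatches(a: str, b: str, limit: int) -> int:
    """Hamming mismatches between equal-length strings, early exit past limit."""
    n = 0
    for x, y in zip(a, b):
        if x != y:
            n += 1
            if n > limit:
                return n
    return n


def extract_variable_region(
    read: QualityRead,
    design: LibraryDesign,
    max_flank_mismatch: int = 2,
) -> tuple[str | None, RejectionReason | None]:
    """Recover the variable region between the two fixed flanks.

    Flank matching is substitution-only (no indels) and anchored: the 5'
    flank is sought starting at offsets 0..4, and the 3' flank at the
    position implied by the design's variable length +/- 2 nt.  Returns
    ``(region, None)`` on success or ``(None, reason)`` on rejection.
    """
    bases = normalize_dna(read.bases)
    f5, f3 = design.flank5, design.flank3
    start5 = None
    for off in range(0, 5):
        if off + len(f5) > len(bases):
            break
        if _mismatches(bases[off : off + len(f5)], f5, max_flank_mismatch) <= max_flank_mismatch:
            start5 = off
            break
    if start5 is None:
        return None, RejectionReason.FLANK5_MISSING
    core_start = start5 + len(f5)
    start3 = None
    for delta in (0, -1, 1, -2, 2):
        pos = core_start + design.var_len + delta
        if pos < core_start or pos + len(f3) > len(bases):
            continue
        if _mismatches(bases[pos : pos + len(f3)], f3, max_flank_mismatch) <= max_flank_mismatch:
            start3 = pos
            break
    if start3 is None:
        return None, RejectionReason.FLANK3_MISSING
    region = bases[core_start:start3]
    if len(region) != design.var_len:
        return None, RejectionReason.BAD_LENGTH
    return region, None


def filter_and_extract(
    reads: Iterable[QualityRead],
    design: LibraryDesign,
    qmin: int = 30,
    max_flank_mismatch: int = 2,
    report: ExtractionReport | None = None,
) -> Iterator[str]:
    """Quality-filter then extract; rejections are tallied, not fatal."""
    if report is None:
        report = ExtractionReport()
    for read in reads:
        if not quality_pass(read, qmin):
            report.reject(RejectionReason.LOW_QUALITY)
            continue
        region, reason = extract_variable_region(read, design, max_flank_mismatch)
        if region is None:
            report.reject(reason)
            continue
        report.accept()
        yield region


def write_count_fasta(
    counts: dict[str, int],
    handle: TextIO,
    chemistry: Chemistry = Chemistry.DNA,
) -> None:
    """Write unique sequences as FASTA with ``>seq_<rank>-<count>`` headers,
    most abundant first (ties broken lexicographically)."""
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    for rank, (seq, count) in enumerate(ranked, start=1):
        handle.write(f">seq_{rank}-{count}\n{to_chemistry(seq, chemistry)}\n")
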