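"""Synthetic SELEX: selection dynamics, sequencing, competition, gene lists.

The simulator stands in for the wet-lab selection so that every stage
of the analysis can be exercised with a known ground truth.  It
emulates:

* a random-flanked library (fixed 5'/3' primers around an i.i.d.
  uniform random core), optionally carrying planted motif families;
* round-over-round affinity selection: each molecule is retained with
  probability ``nonspecific_retention`` times its selection weight
  (``selection_weight`` for planted matches, 1 otherwise), then the
  survivors are resampled with replacement back to the pool size
  (amplification).  The expected frequency of a planted class with
  advantage s therefore follows the recursion f' = s f / (s f + 1 - f):
  a few rounds of apparent latency, then takeoff;
* Phred-scored sequencing with substitution errors and a configurable
  fraction of reads that fail the all-bases Q>=30 filter;
* competition mixtures with known per-aptamer retention ratios;
* gene universes with a planted overlap.

All randomness flows through one ``numpy.random.Generator`` seeded from
the config, so every output is reproducible bit-for-bit.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .aptamers import G2_CONSENSUS, RNA_DESIGN
from .competition import CompetitionTable
from .reads import LibraryDesign

__all__ = [
    "PlantedMotif",
    "SelexSimConfig",
    "GroundTruthLedger",
    "SelexRun",
    "generate_initial_pool",
    "selection_round",
    "selection_recursion",
    "sequence_pool",
    "run_selex",
    "simulate_competition",
    "simulate_gene_lists",
    "g2_study_config",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class PlantedMotif:
    """A sequence class with a selection advantage planted in the pool.

    Either ``seed_sequences`` fixes the founder variable regions
    explicitly (a family in the clustering sense: identical molecules
    whose read-level variants arise from sequencing error), or
    ``pattern`` (N = any base) is instantiated into ``n_founders``
    random founders each embedding the motif at a random offset.
    """

    pattern: str | None = None
    selection_weight: float = 10.0
    initial_fraction: float = 1e-3
    seed_sequences: tuple[str, ...] | None = None
    n_founders: int = 1

    def __post_init__(self) -> None:
        if self.selection_weight < 1:
            raise ValueError("selection_weight must be >= 1")
        if not 0 <= self.initial_fraction <= 1:
            raise ValueError("initial_fraction must lie in [0, 1]")
        if self.pattern is None and not self.seed_sequences:
            raise ValueError("need a pattern or explicit seed_sequences")

    def matcher(self) -> Callable[[str], bool]:
        if self.pattern is not None:
            rx = re.compile(self.pattern.upper().replace("U", "T").replace("N", "[ACGT]"))
            return lambda s: rx.search(s) is not None
        seeds = set(self.seed_sequences)
        return lambda s: s in seeds


@dataclass(frozen=True)
class SelexSimConfig:
    design: LibraryDesign = RNA_DESIGN
    pool_size: int = 100_000
    rounds: int = 6
    planted: tuple[PlantedMotif, ...] = ()
    nonspecific_retention: float = 0.05
    per_base_error: float = 0.002
    reads_per_round: int = 100_000
    quality_fail_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pool_size <= 0 or self.reads_per_round <= 0:
            raise ValueError("pool_size and reads_per_round must be positive")
        if not 0 < self.nonspecific_retention < 1:
            raise ValueError("nonspecific_retention must lie in (0, 1)")
        for p in (self.per_base_error, self.quality_fail_fraction):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        for m in self.planted:
            if m.pattern is not None and len(m.pattern) > self.design.var_len:
                raise ValueError("planted motif longer than the variable region")
            if m.seed_sequences and any(
                len(s) != self.design.var_len for s in m.seed_sequences
            ):
                raise ValueError("seed sequences must have the design's var_len")


@dataclass
class GroundTruthLedger:
    """What the simulator actually did, for checking the analysis against."""

    planted_freq_by_round: list[dict[int, float]] = field(default_factory=list)
    founders: list[tuple[str, ...]] = field(default_factory=list)
    sampled_counts_by_round: list[Counter] = field(default_factory=list)
    true_fe: dict[str, float] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "planted_freq_by_round": [
                {str(r): f for r, f in m.items()} for m in self.planted_freq_by_round
            ],
            "founders": [list(f) for f in self.founders],
            "true_fe": dict(self.true_fe),
        }


@dataclass
class SelexRun:
    config: SelexSimConfig
    fastq_by_round: list[str]
    ledger: GroundTruthLedger


def _random_regions(rng: np.random.Generator, n: int, length: int) -> list[str]:
    if n <= 0:
        return []
    arr = _BASES[rng.integers(0, 4, size=(n, length))]
    return [bytes(row).decode() for row in arr]


def _instantiate(pattern: str, rng: np.random.Generator) -> str:
    out = []
    for ch in pattern.upper().replace("U", "T"):
        out.append(ch if ch != "N" else "ACGT"[rng.integers(0, 4)])
    return "".join(out)


def generate_initial_pool(
    config: SelexSimConfig, rng: np.random.Generator | None = None
) -> tuple[list[str], list[tuple[str, ...]]]:
    """Round-0 pool of variable regions plus the founders per planted motif.

    The unplanted majority is i.i.d. uniform over ACGT; each planted
    motif contributes ``initial_fraction * pool_size`` copies of its
    founders.  Deterministic given the config seed.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    pool: list[str] = []
    founders_all: list[tuple[str, ...]] = []
    n_planted_total = 0
    for motif in config.planted:
        n = int(round(motif.initial_fraction * config.pool_size))
        n_planted_total += n
        if motif.seed_sequences:
            founders = tuple(s.upper().replace("U", "T") for s in motif.seed_sequences)
        else:
            founders = []
            core = _instantiate(motif.pattern, rng)
            for _ in range(motif.n_founders):
                if motif.n_founders > 1:
                    core = _instantiate(motif.pattern, rng)
                pad = config.design.var_len - len(core)
                off = int(rng.integers(0, pad + 1)) if pad else 0
                bg = _random_regions(rng, 1, config.design.var_len)[0]
                founders.append(bg[:off] + core + bg[off + len(core) :])
            founders = tuple(founders)
        founders_all.append(founders)
        for i in range(n):
            pool.append(founders[i % len(founders)])
    pool.extend(_random_regions(rng, config.pool_size - n_planted_total, config.design.var_len))
    return pool, founders_all


def selection_recursion(f: float, s: float, rounds: int = 1) -> float:
    """Expected planted frequency after ``rounds`` of f' = s f/(s f + 1 - f)."""
    for _ in range(rounds):
        f = s * f / (s * f + 1.0 - f)
    return f


def selection_round(
    pool: Sequence[str], config: SelexSimConfig, rng: np.random.Generator
) -> list[str]:
    """One selection + amplification cycle.

    Each molecule survives a Bernoulli draw with probability
    ``nonspecific_retention`` scaled by its selection weight (capped at
    1), and the survivors are resampled with replacement back to
    ``pool_size``.  If nothing survives — possible only at extreme
    parameters — the round fails loudly.
    """
    if not pool:
        raise ValueError("cannot select from an empty pool")
    probs = np.full(len(pool), config.nonspecific_retention)
    for motif in config.planted:
        match = motif.matcher()
        mask = np.fromiter((match(s) for s in pool), dtype=bool, count=len(pool))
        probs[mask] = np.minimum(1.0, config.nonspecific_retention * motif.selection_weight)
    survivors = np.nonzero(rng.random(len(pool)) < probs)[0]
    if survivors.size == 0:
        raise RuntimeError("no molecule survived the selection round")
    resampled = rng.choice(survivors, size=config.pool_size, replace=True)
    return [pool[i] for i in resampled]


def _planted_frequency(pool: Sequence[str], config: SelexSimConfig) -> dict[int, float]:
    out = {}
    for i, motif in enumerate(config.planted):
        match = motif.matcher()
        out[i] = sum(1 for s in pool if match(s)) / len(pool)
    return out


def sequence_pool(
    pool: Sequence[str],
    config: SelexSimConfig,
    rng: np.random.Generator,
    round_index: int = 0,
) -> tuple[str, Counter]:
    """Sequence a pool: FASTQ text plus the error-free sampled multiset.

    ``reads_per_round`` molecules are drawn with replacement, flanks are
    attached, substitution errors strike each base with probability
    ``per_base_error``, and a ``quality_fail_fraction`` of reads get one
    below-30 quality so they fail the downstream filter.
    """
    n = config.reads_per_round
    idx = rng.integers(0, len(pool), size=n)
    sampled = Counter(pool[i] for i in idx)
    f5, f3 = config.design.flank5, config.design.flank3
    read_len = config.design.read_length

    quals = rng.integers(30, 41, size=(n, read_len), dtype=np.int16)
    fail = rng.random(n) < config.quality_fail_fraction
    fail_pos = rng.integers(0, read_len, size=n)
    fail_q = rng.integers(2, 30, size=n)
    quals[fail, fail_pos[fail]] = fail_q[fail]
    qual_bytes = (quals + 33).astype(np.uint8)

    n_errors = rng.binomial(read_len, config.per_base_error, size=n)
    records: list[str] = []
    for r in range(n):
        seq = f5 + pool[idx[r]] + f3
        if n_errors[r]:
            chars = list(seq)
            for pos in rng.integers(0, read_len, size=n_errors[r]):
                old = chars[pos]
                choices = [b for b in "ACGT" if b != old]
                chars[pos] = choices[rng.integers(0, 3)]
            seq = "".join(chars)
        records.append(
            f"@sim_r{round_index}_{r}\n{seq}\n+\n{bytes(qual_bytes[r]).decode()}\n"
        )
    return "".join(records), sampled


def run_selex(config: SelexSimConfig) -> SelexRun:
    """Full simulated experiment: rounds 0..R sequenced, truth recorded."""
    rng = np.random.default_rng(config.seed)
    pool, founders = generate_initial_pool(config, rng)
    ledger = GroundTruthLedger(founders=founders)
    fastqs: list[str] = []
    for r in range(config.rounds + 1):
        ledger.planted_freq_by_round.append(_planted_frequency(pool, config))
        fastq, sampled = sequence_pool(pool, config, rng, round_index=r)
        fastqs.append(fastq)
        ledger.sampled_counts_by_round.append(sampled)
        if r < config.rounds:
            pool = selection_round(pool, config, rng)
    return SelexRun(config, fastqs, ledger)


def g2_study_config(seed: int = 0, **overrides) -> SelexSimConfig:
    """Standard study conditions: one planted G2-rich family, advantage 10,
    initial frequency 1e-3, six rounds at 100k reads/round.

    The founder is a fixed instantiation of the G2-rich consensus motif
    embedded in a random 50-nt background derived from the seed.
    """
    rng = np.random.default_rng(seed)
    core = _instantiate(G2_CONSENSUS, rng)
    bg = _random_regions(rng, 1, RNA_DESIGN.var_len)[0]
    off = int(rng.integers(0, RNA_DESIGN.var_len - len(core) + 1))
    founder = bg[:off] + core + bg[off + len(core) :]
    planted = PlantedMotif(
        selection_weight=10.0, initial_fraction=1e-3, seed_sequences=(founder,)
    )
    cfg = SelexSimConfig(design=RNA_DESIGN, planted=(planted,), seed=seed)
    return replace(cfg, **overrides) if overrides else cfg


def simulate_competition(
    true_retention: dict[str, float],
    replicates: int,
    depth: int,
    seed: int | np.random.Generator = 0,
    condition: str = "simulated",
) -> tuple[list[CompetitionTable], dict[str, float]]:
    """Multinomial competition counts with known retention ratios.

    Returns the per-replicate tables and the ledger of true FE values
    (retention relative to ``scr50`` when present, else to the first
    aptamer).
    """
    if replicates <= 0:
        raise ValueError("replicates must be positive")
    if any(v <= 0 for v in true_retention.values()):
        raise ValueError("retention values must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ids = list(true_retention)
    p = np.array([true_retention[a] for a in ids], dtype=float)
    p /= p.sum()
    tables = [
        CompetitionTable(
            condition, rep, dict(zip(ids, map(int, rng.multinomial(depth, p))))
        )
        for rep in range(1, replicates + 1)
    ]
    ref = "scr50" if "scr50" in true_retention else ids[0]
    true_fe = {a: true_retention[a] / true_retention[ref] for a in ids}
    return tables, true_fe


def simulate_gene_lists(
    universe_n: int, n1: int, n2: int, k_true: int, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Two gene lists over a universe of ``universe_n`` ids sharing exactly
    ``k_true`` genes."""
    if k_true > min(n1, n2):
        raise ValueError("k_true cannot exceed the smaller list")
    if n1 + n2 - k_true > universe_n:
        raise ValueError("universe too small for the requested lists")
    rng = np.random.default_rng(seed)
    ids = rng.permutation(universe_n)
    shared = ids[:k_true]
    only1 = ids[k_true : n1]
    only2 = ids[n1 : n1 + (n2 - k_true)]
    name = "GENE{:06d}".format
    list1 = sorted(name(i) for i in np.concatenate([shared, only1]))
    list2 = sorted(name(i) for i in np.concatenate([shared, only2]))
    return list1, list2
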