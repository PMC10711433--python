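"""Levenshtein-distance family clustering of enriched sequences.

Detected sequences are grouped into families: a family collects every
sequence within a fixed edit distance (default 10 — substitutions,
insertions and deletions all count 1) of an abundant seed.  Clustering
is greedy and abundance-ordered, which is deterministic and standard
for aptamer pools: the most abundant unassigned sequence seeds the next
family and absorbs all unassigned sequences within the threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence, TextIO

import edlib

from .enrichment import PWM, SequenceSeries, align_offset, weighted_pwm

__all__ = [
    "Family",
    "levenshtein",
    "cluster_families",
    "family_count_per_round",
    "family_logo",
    "write_families_tsv",
    "families_summary",
]


def levenshtein(a: str, b: str) -> int:
    """Edit distance: minimal substitutions + insertions + deletions."""
    if a == b:
        return 0
    if not a:
        return len(b)
    if not b:
        return len(a)
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


@dataclass
class Family:
    """A cluster of similar sequences treated as one enrichment unit."""

    family_id: str
    seed: str
    members: list[str]
    abundance_by_round: dict[int, float]
    internal_diameter: int

    def __post_init__(self) -> None:
        if self.seed not in self.members:
            raise ValueError("family seed must be one of its members")


def _diameter(members: Sequence[str]) -> int:
    """Max pairwise Levenshtein distance; brute force (families are small)."""
    worst = 0
    for i, a in enumerate(members):
        for b in members[i + 1 :]:
            d = levenshtein(a, b)
            if d > worst:
                worst = d
    return worst


def cluster_families(
    series: Sequence[SequenceSeries],
    last_round: int,
    threshold: int = 10,
    compute_diameter: bool = True,
) -> list[Family]:
    """Greedy abundance-ordered clustering at a fixed edit-distance threshold.

    Repeatedly the unassigned sequence with the highest last-round
    frequency (ties broken lexicographically) becomes a seed, and every
    unassigned sequence within ``threshold`` of it joins that family.
    Families are returned sorted by last-round abundance descending.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    by_seq = {s.sequence: s for s in series}
    order = sorted(
        by_seq.values(), key=lambda s: (-s.freq_by_round.get(last_round, 0.0), s.sequence)
    )
    unassigned = {s.sequence for s in order}
    rounds = sorted({r for s in series for r in s.freq_by_round})
    families: list[Family] = []
    for cand in order:
        if cand.sequence not in unassigned:
            continue
        seed = cand.sequence
        members = [s for s in unassigned if levenshtein(seed, s) <= threshold]
        unassigned.difference_update(members)
        members.sort()
        abundance = {
            r: float(sum(by_seq[m].freq_by_round.get(r, 0.0) for m in members))
            for r in rounds
        }
        families.append(
            Family(
                family_id="",
                seed=seed,
                members=members,
                abundance_by_round=abundance,
                internal_diameter=_diameter(members) if compute_diameter else -1,
            )
        )
    families.sort(
        key=lambda f: (-f.abundance_by_round.get(last_round, 0.0), f.seed)
    )
    for i, fam in enumerate(families):
        fam.family_id = f"F{i:04d}"
    return families


def family_count_per_round(
    families: Sequence[Family], min_freq: float
) -> dict[int, int]:
    """Number of families whose abundance exceeds ``min_freq`` per round."""
    rounds = sorted({r for f in families for r in f.abundance_by_round})
    return {
        r: sum(1 for f in families if f.abundance_by_round.get(r, 0.0) > min_freq)
        for r in rounds
    }


def family_logo(
    families: Sequence[Family],
    top_n: int,
    last_round: int | None = None,
    member_weighted: bool = False,
) -> PWM:
    """Abundance-weighted PWM over the top ``top_n`` family seeds.

    Seeds are ungapped-aligned (offset -3..+3, ties to 0) against the
    most abundant family's seed.  With ``member_weighted`` every member
    contributes its own frequency instead of the whole family's
    abundance going to the seed.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    if last_round is None:
        last_round = max(r for f in families for r in f.abundance_by_round)
    ranked = sorted(
        families, key=lambda f: (-f.abundance_by_round.get(last_round, 0.0), f.seed)
    )[:top_n]
    ref = ranked[0].seed
    aligned: list[tuple[str, int, float]] = []
    for fam in ranked:
        weight = fam.abundance_by_round.get(last_round, 0.0)
        if member_weighted:
            share = weight / len(fam.members) if fam.members else 0.0
            for m in fam.members:
                aligned.append((m, align_offset(ref, m), share))
        else:
            aligned.append((fam.seed, align_offset(ref, fam.seed), weight))
    if all(w == 0.0 for _, _, w in aligned):
        aligned = [(s, o, 1.0) for s, o, _ in aligned]
    return weighted_pwm(aligned, len(ref))


def write_families_tsv(families: Sequence[Family], handle: TextIO) -> None:
    rounds = sorted({r for f in families for r in f.abundance_by_round})
    header = ["family_id", "seed", "n_members", "internal_diameter"]
    header += [f"abundance_r{r}" for r in rounds]
    handle.write("\t".join(header) + "\n")
    for f in families:
        row = [f.family_id, f.seed, str(len(f.members)), str(f.internal_diameter)]
        row += [f"{f.abundance_by_round.get(r, 0.0):.6g}" for r in rounds]
        handle.write("\t".join(row) + "\n")


def families_summary(families: Sequence[Family]) -> str:
    """JSON summary (id, seed, member count, abundance series, diameter)."""
    payload = [
        {
            "family_id": f.family_id,
            "seed": f.seed,
            "n_members": len(f.members),
            "internal_diameter": f.internal_diameter,
            "abundance_by_round": {str(r): v for r, v in f.abundance_by_round.items()},
        }
        for f in families
    ]
    return json.dumps(payload, indent=2)
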