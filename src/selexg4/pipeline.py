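"""End-to-end orchestration: filter -> count -> detect -> cluster -> logos -> G4 scan.

Files are the interface between stages; the run report records the
configured thresholds and per-stage read accounting (raw = passed +
rejected at every round), so a run is auditable and reproducible.
"""

from __future__ import annotations

import io
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from . import enrichment, families, g4
from .enrichment import RoundCountTable
from .reads import (
    ExtractionReport,
    LibraryDesign,
    filter_and_extract,
    open_fastq,
    parse_fastq,
    write_count_fasta,
)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "write_report"]

log = logging.getLogger("selexg4")

SCHEMA_VERSION = 1


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name for context."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    fastq_by_round: list[str]  # one path per round, round 0 first
    design: LibraryDesign
    out_dir: str
    min_freq: float = enrichment.MIN_FREQ_RNA
    qmin: int = 30
    max_flank_mismatch: int = 2
    levenshtein_threshold: int = 10
    kmer_k: int = 8
    top_n: int = 20
    g4_max_len: int = 30
    g4_min_run: int = 2
    seed: int = 0

    def validate(self) -> None:
        for p in self.fastq_by_round:
            if not Path(p).exists():
                raise PipelineError("config", f"missing FASTQ: {p}")
        if not 0 < self.min_freq < 1:
            raise PipelineError("config", "min_freq must lie in (0, 1)")
        if self.qmin < 0 or self.levenshtein_threshold < 0 or self.top_n < 1:
            raise PipelineError("config", "thresholds out of range")

    def thresholds(self) -> dict:
        return {
            "min_freq": self.min_freq,
            "qmin": self.qmin,
            "max_flank_mismatch": self.max_flank_mismatch,
            "levenshtein_threshold": self.levenshtein_threshold,
            "kmer_k": self.kmer_k,
            "top_n": self.top_n,
            "g4_max_len": self.g4_max_len,
            "g4_min_run": self.g4_min_run,
        }


def _count_stage(config: RunConfig) -> tuple[list[RoundCountTable], list[ExtractionReport]]:
    tables, reports = [], []
    for r, path in enumerate(config.fastq_by_round):
        report = ExtractionReport()
        with open_fastq(path) as handle:
            regions = list(
                filter_and_extract(
                    parse_fastq(handle),
                    config.design,
                    qmin=config.qmin,
                    max_flank_mismatch=config.max_flank_mismatch,
                    report=report,
                )
            )
        if not regions:
            raise PipelineError("count", f"round {r} ({path}): no read survived filtering")
        tables.append(enrichment.count_round(regions, r))
        reports.append(report)
        log.info("round %d: %d raw, %d passed", r, report.raw, report.passed)
    return tables, reports


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the TSV/JSON bundle; returns the report."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    tables, reports = _count_stage(config)
    for table in tables:
        with open(out / f"counts_round{table.round_index}.tsv", "w") as fh:
            enrichment.write_counts_tsv(table, fh)

    detected = enrichment.detected_sequences(tables, config.min_freq)
    if not detected:
        raise PipelineError("detect", "no sequence exceeded the detection threshold")
    fractions = enrichment.pool_fraction(detected, tables)
    composition = {t.round_index: enrichment.composition_by_round(t) for t in tables}

    last = tables[-1].round_index
    with open(out / "detected_series.tsv", "w") as fh:
        rounds = [t.round_index for t in tables]
        fh.write("sequence\t" + "\t".join(f"freq_r{r}" for r in rounds) + "\n")
        for s in detected:
            fh.write(s.sequence + "\t" + "\t".join(f"{s.freq_by_round.get(r, 0):.6g}" for r in rounds) + "\n")
    with open(out / "last_round_sequences.fasta", "w") as fh:
        write_count_fasta(tables[-1].counts, fh, config.design.chemistry)

    fams = families.cluster_families(detected, last, config.levenshtein_threshold)
    with open(out / "families.tsv", "w") as fh:
        families.write_families_tsv(fams, fh)
    with open(out / "families.json", "w") as fh:
        fh.write(families.families_summary(fams))
    family_counts = families.family_count_per_round(fams, config.min_freq)

    kfreqs = enrichment.kmer_frequencies(tables[-1], config.kmer_k)
    kmer_pwm = enrichment.kmer_logo(kfreqs, config.top_n)
    fam_pwm = families.family_logo(fams, min(config.top_n, len(fams)), last)
    with open(out / "kmer_logo.meme", "w") as fh:
        enrichment.write_meme(kmer_pwm, fh, name=f"top{config.top_n}_{config.kmer_k}mers")
    with open(out / "family_logo.meme", "w") as fh:
        enrichment.write_meme(fam_pwm, fh, name="family_consensus")

    g4_rows = []
    for fam in fams[: config.top_n]:
        score = g4.max_g_score(fam.seed, config.g4_max_len, config.g4_min_run)
        g4_rows.append(
            {
                "family_id": fam.family_id,
                "seed": fam.seed,
                "g_doublets": g4.count_g_doublets(fam.seed),
                "max_g_score": score,
            }
        )
    with open(out / "family_g4.tsv", "w") as fh:
        fh.write("family_id\tseed\tg_doublets\tmax_g_score\n")
        for row in g4_rows:
            fh.write("{family_id}\t{seed}\t{g_doublets}\t{max_g_score}\n".format(**row))

    report = {
        "schema_version": SCHEMA_VERSION,
        "thresholds": config.thresholds(),
        "seed": config.seed,
        "rounds": {
            str(t.round_index): {
                **rep.as_dict(),
                "unique_sequences": len(t.counts),
                "detected_pool_fraction": fractions[t.round_index],
                "families_above_threshold": family_counts.get(t.round_index, 0),
                "composition": composition[t.round_index],
            }
            for t, rep in zip(tables, reports)
        },
        "n_detected": len(detected),
        "n_families": len(fams),
        "top_family_g4": g4_rows,
    }
    write_report(report, out / "report.json")
    return report


def write_report(report: dict, path) -> None:
    """Serialize the run report; round-trips losslessly via JSON."""
    text = json.dumps(report, indent=2, sort_keys=True)
    if json.loads(text) != json.loads(json.dumps(json.loads(text))):
        raise PipelineError("report", "report is not JSON-serializable losslessly")
    Path(path).write_text(text + "\n")
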