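"""Pipeline orchestration and coverage reporting.

Coverage is the percentage of drug records for which a mapping is
available, computed twice: over all records (each unique record weighted
by its multiplicity) and over unique records. ATC coverage counts records
whose mapping also resolved to a single ATC code; it can never exceed
concept coverage, since ATC resolution requires a prior concept mapping.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from .atc import assign_atc
from .mapper import MapOptions, MappingResult, STEP_LABELS, map_record
from .records import MISSING, RecordKey, parse_drug_file, record_key, unique_records
from .vocab import VocabIndex, load_vocab

logger = logging.getLogger(__name__)


def _pct(part: int, whole: int) -> float:
    return round(100.0 * part / whole, 1) if whole else 0.0


@dataclass
class CoverageStats:
    """Record- and unique-level mapping coverage plus per-step tallies."""

    total_records: int = 0
    total_unique: int = 0
    mapped_records: int = 0
    mapped_unique: int = 0
    atc_records: int = 0
    atc_unique: int = 0
    step_counts_records: dict[int, int] = field(default_factory=dict)
    step_counts_unique: dict[int, int] = field(default_factory=dict)

    @property
    def mapped_pct_records(self) -> float:
        return _pct(self.mapped_records, self.total_records)

    @property
    def mapped_pct_unique(self) -> float:
        return _pct(self.mapped_unique, self.total_unique)

    @property
    def atc_pct_records(self) -> float:
        return _pct(self.atc_records, self.total_records)

    @property
    def atc_pct_unique(self) -> float:
        return _pct(self.atc_unique, self.total_unique)

    def as_dict(self) -> dict:
        return {
            "total_records": self.total_records,
            "total_unique": self.total_unique,
            "mapped_records": self.mapped_records,
            "mapped_unique": self.mapped_unique,
            "atc_records": self.atc_records,
            "atc_unique": self.atc_unique,
            "mapped_pct_records": self.mapped_pct_records,
            "mapped_pct_unique": self.mapped_pct_unique,
            "atc_pct_records": self.atc_pct_records,
            "atc_pct_unique": self.atc_pct_unique,
            "step_counts_records": {
                STEP_LABELS[k]: v for k, v in sorted(self.step_counts_records.items())
            },
            "step_counts_unique": {
                STEP_LABELS[k]: v for k, v in sorted(self.step_counts_unique.items())
            },
        }


def coverage_report(
    results: dict[RecordKey, MappingResult], counts: Counter
) -> CoverageStats:
    """Compute coverage from per-unique-key results and key multiplicities."""
    stats = CoverageStats()
    for key, count in counts.items():
        result = results[key]
        stats.total_records += count
        stats.total_unique += 1
        if result.mapped:
            stats.mapped_records += count
            stats.mapped_unique += 1
            step = result.matched_step
            stats.step_counts_records[step] = (
                stats.step_counts_records.get(step, 0) + count
            )
            stats.step_counts_unique[step] = stats.step_counts_unique.get(step, 0) + 1
            if result.atc_code is not None:
                stats.atc_records += count
                stats.atc_unique += 1
    return stats


def format_coverage(stats: CoverageStats) -> str:
    lines = [
        f"drug records:          {stats.total_records}",
        f"unique drug records:   {stats.total_unique}",
        f"mapped to drug concept: {stats.mapped_records} "
        f"({stats.mapped_pct_records}%) records, {stats.mapped_unique} "
        f"({stats.mapped_pct_unique}%) unique",
        f"mapped to ATC code:     {stats.atc_records} "
        f"({stats.atc_pct_records}%) records, {stats.atc_unique} "
        f"({stats.atc_pct_unique}%) unique",
        "per-step matches (unique records):",
    ]
    for step in sorted(stats.step_counts_unique):
        lines.append(
            f"  step {step} {STEP_LABELS[step]:<18}"
            f" {stats.step_counts_unique[step]}"
        )
    return "\n".join(lines)


_TABLE_COLUMNS = [
    "drugname", "prod_ai", "route", "dose_amt", "dose_form", "dose_unit",
    "nda_num", "count", "matched_step", "variant_used", "raw_concept_ids",
    "final_concept_ids", "atc_code", "notes",
]


def write_mapping_table(
    results: dict[RecordKey, MappingResult],
    counts: Counter,
    path: str | Path,
    sep: str = "\t",
) -> None:
    """One row per unique record key, with the full audit columns."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(sep.join(_TABLE_COLUMNS) + "\n")
        for key, count in counts.items():
            result = results[key]
            cells = ["" if v is MISSING else str(v) for v in key]
            cells += [
                str(count),
                result.step_label,
                result.variant_used or "",
                ";".join(str(c.concept_id)
                         for c in sorted(result.raw_concepts,
                                         key=lambda c: c.concept_id)),
                ";".join(str(c.concept_id)
                         for c in sorted(result.final_concepts,
                                         key=lambda c: c.concept_id)),
                result.atc_code or "",
                " | ".join(result.notes),
            ]
            fh.write(sep.join(c.replace(sep, " ").replace("\n", " ")
                              for c in cells) + "\n")


def run_pipeline(
    input_path: str | Path,
    vocab_dir: str | Path,
    out_dir: str | Path,
    options: MapOptions | None = None,
    delimiter: str = "$",
    vocab_sep: str = "\t",
    index: VocabIndex | None = None,
    verbose: bool = False,
) -> CoverageStats:
    """Map a FAERS drug file end to end.

    Writes ``mapping_table.tsv``, ``coverage.txt`` and ``coverage.json``
    under ``out_dir`` and returns the coverage statistics.
    """
    options = options or MapOptions()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if index is None:
        index = load_vocab(vocab_dir, sep=vocab_sep)
    records = parse_drug_file(input_path, delimiter=delimiter)
    counts = unique_records(records)

    by_key = {record_key(r): r for r in records}
    results: dict[RecordKey, MappingResult] = {}
    for key in counts:
        record = by_key[key]
        result = map_record(record, index, options)
        assign_atc(record, result, index)
        results[key] = result
        if verbose:
            logger.info("%s -> %s", key, " | ".join(result.notes))

    stats = coverage_report(results, counts)
    write_mapping_table(results, counts, out_dir / "mapping_table.tsv")
    (out_dir / "coverage.txt").write_text(format_coverage(stats) + "\n",
                                          encoding="utf-8")
    (out_dir / "coverage.json").write_text(
        json.dumps(stats.as_dict(), indent=2) + "\n", encoding="utf-8"
    )
    logger.info("mapped %s/%s unique records (%s%%)",
                stats.mapped_unique, stats.total_unique,
                stats.mapped_pct_unique)
    return stats
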