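"""Reading FAERS DRUG files and defining drug-record identity.

FAERS quarterly extracts ship drug data as ``$``-delimited ASCII with a
header row and no quoting. Drug names, active ingredients, routes and dose
fields are free text; empty cells mean "not reported". A *unique drug
record* is the combination of the seven descriptive fields
(drugname, prod_ai, route, dose_amt, dose_form, dose_unit, nda_num), with
a missing value distinct from every reported value.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, fields as dc_fields
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

#: Sentinel for an unreported field. Empty cells, whitespace-only cells and
#: the literal token "NULL" (any case) all parse to MISSING; after parsing a
#: field is never the empty string.
MISSING = None

#: The seven fields whose combination defines a unique drug record.
KEY_FIELDS = (
    "drugname",
    "prod_ai",
    "route",
    "dose_amt",
    "dose_form",
    "dose_unit",
    "nda_num",
)

#: Columns accepted as the report identifier, in order of preference.
REPORT_ID_COLUMNS = ("primaryid", "isr", "report_id")


@dataclass(frozen=True, slots=True)
class DrugRecord:
    """One row of a FAERS DRUG file — the unit being mapped.

    Field values keep their original casing and internal whitespace;
    cleaning is the normalizer's job, not the parser's.
    """

    report_id: str | None = MISSING
    drug_seq: str | None = MISSING
    drugname: str | None = MISSING
    prod_ai: str | None = MISSING
    route: str | None = MISSING
    dose_amt: str | None = MISSING
    dose_form: str | None = MISSING
    dose_unit: str | None = MISSING
    nda_num: str | None = MISSING


#: 7-tuple of the key fields; MISSING equal only to MISSING.
RecordKey = tuple


def record_key(record: DrugRecord) -> RecordKey:
    """Project a record onto its 7-field identity key.

    Comparison is byte-exact on the raw field values (no case folding or
    trimming): uniqueness is defined on the FAERS fields as reported, and
    MISSING is a distinct value equal only to MISSING.
    """
    return tuple(getattr(record, f) for f in KEY_FIELDS)


def unique_records(records: Sequence[DrugRecord]) -> Counter:
    """Group records by their key; returns ``Counter`` of RecordKey -> count.

    The sum of counts equals ``len(records)``.
    """
    return Counter(record_key(r) for r in records)


def _parse_cell(cell: str) -> str | None:
    stripped = cell.strip()
    if not stripped or stripped.upper() == "NULL":
        return MISSING
    return cell


class ParseError(ValueError):
    """A drug file could not be parsed (e.g. required header column absent)."""


def _read_text(path: Path, encoding: str | None) -> str:
    data = path.read_bytes()
    if encoding is not None:
        return data.decode(encoding)
    try:
        return data.decode("utf-8")
    except UnicodeDecodeError:
        return data.decode("latin-1")


def parse_drug_file(
    path: str | Path,
    delimiter: str = "$",
    encoding: str | None = None,
) -> list[DrugRecord]:
    """Parse a FAERS-format DRUG file into :class:`DrugRecord` objects.

    The first line must be a header naming the seven key fields plus a
    report identifier. Unknown columns are ignored. Lines whose cell count
    does not match the header are skipped and logged with their line
    number — never silently dropped.

    Raises
    ------
    ParseError
        If a required header column is absent.
    """
    path = Path(path)
    text = _read_text(path, encoding)
    lines = text.splitlines()
    if not lines:
        return []

    header = [h.strip().lower() for h in lines[0].split(delimiter)]
    col_pos = {name: i for i, name in enumerate(header)}

    missing_cols = [f for f in KEY_FIELDS if f not in col_pos]
    if missing_cols:
        raise ParseError(
            f"{path}: required column(s) missing from header: "
            + ", ".join(missing_cols)
        )
    report_col = next((c for c in REPORT_ID_COLUMNS if c in col_pos), None)
    if report_col is None:
        raise ParseError(
            f"{path}: no report identifier column found "
            f"(expected one of {', '.join(REPORT_ID_COLUMNS)})"
        )

    ncols = len(header)
    records: list[DrugRecord] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split(delimiter)
        if len(cells) != ncols:
            logger.warning(
                "%s:%d: expected %d cells, found %d — line skipped",
                path, lineno, ncols, len(cells),
            )
            continue

        def get(col: str) -> str | None:
            pos = col_pos.get(col)
            return _parse_cell(cells[pos]) if pos is not None else MISSING

        records.append(
            DrugRecord(
                report_id=get(report_col),
                drug_seq=get("drug_seq"),
                **{f: get(f) for f in KEY_FIELDS},
            )
        )
    return records


def write_drug_file(
    records: Iterable[DrugRecord],
    path: str | Path,
    delimiter: str = "$",
) -> None:
    """Serialize records in the FAERS dialect (MISSING -> empty cell).

    ``parse_drug_file(write_drug_file(records))`` round-trips records whose
    field values contain no delimiter characters.
    """
    cols = ["primaryid", "drug_seq", *KEY_FIELDS]
    attr = {"primaryid": "report_id"}
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(delimiter.join(cols) + "\n")
        for rec in records:
            cells = []
            for col in cols:
                val = getattr(rec, attr.get(col, col))
                cells.append("" if val is MISSING else str(val))
            fh.write(delimiter.join(cells) + "\n")
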