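"""Reading and writing FAERS-dialect quarterly ASCII tables.

The FDA distributes FAERS quarterly extracts as plain-text tables with a
single header line and ``$``-separated fields, one record per line, no
quoting.  This module parses the four tables the screening pipeline
consumes (DEMO, DRUG, REAC, OUTC) into :class:`pandas.DataFrame` objects
with normalised lower-case column names, and writes the same dialect back
out (the synthetic generator emits through :func:`write_table`, so a
round trip through disk is the identity).

Because the raw dialect has no quoting, a literal delimiter inside a free
-text field (drug names do contain ``$`` occasionally) is backslash-escaped
on write (``$`` -> ``\\$``, ``\\`` -> ``\\\\``) and unescaped on read.

Header names are matched case-insensitively; FAERS changed header case
across years.  No value transformation happens here beyond date validation
flags — unit conversion, deduplication and filtering are downstream
concerns, so attrition stays auditable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd

DELIMITER = "$"

_ESCAPE_RE = re.compile(r"\\(.)")


class TableSchema(str, Enum):
    """The four FAERS quarterly tables the pipeline consumes."""

    DEMO = "DEMO"
    DRUG = "DRUG"
    REAC = "REAC"
    OUTC = "OUTC"


#: required columns per schema, plus optional columns recognised when present.
#: Country may live in OCCR_COUNTRY (occurrence) or REPORTER_COUNTRY depending
#: on the quarter; both are surfaced and merged downstream.
REQUIRED_COLUMNS: Mapping[TableSchema, tuple[str, ...]] = {
    TableSchema.DEMO: ("primaryid", "caseid", "fda_dt", "sex", "age", "age_cod"),
    TableSchema.DRUG: ("primaryid", "drug_seq", "role_cod", "drugname"),
    TableSchema.REAC: ("primaryid", "pt"),
    TableSchema.OUTC: ("primaryid", "outc_cod"),
}

OPTIONAL_COLUMNS: Mapping[TableSchema, tuple[str, ...]] = {
    TableSchema.DEMO: ("occr_country", "reporter_country", "occp_cod"),
    TableSchema.DRUG: ("prod_ai",),
    TableSchema.REAC: (),
    TableSchema.OUTC: (),
}

ROLE_CODES = frozenset({"PS", "SS", "C", "I"})
OUTCOME_CODES = frozenset({"DE", "LT", "HO", "DS", "CA", "RI", "OT"})
SEX_CODES = frozenset({"M", "F", "UNK"})
AGE_CODES = frozenset({"DEC", "YR", "MON", "WK", "DY", "HR"})


@dataclass
class ParseReport:
    """Accounting of one :func:`read_table` call.

    ``rows_skipped`` counts lines with more fields than the header (the
    delimiter dialect cannot attribute the extras); ``rows_incomplete``
    counts lines with fewer fields, which are retained with the trailing
    fields flagged missing.  The parser never invents rows:
    ``rows_read <= line count - 1``.
    """

    path: str
    schema: TableSchema
    rows_read: int = 0
    rows_skipped: int = 0
    rows_incomplete: int = 0
    bad_dates: int = 0
    messages: list[str] = field(default_factory=list)


def _unescape(s: str) -> str:
    return _ESCAPE_RE.sub(r"\1", s)


def _escape(s: str) -> str:
    return s.replace("\\", "\\\\").replace(DELIMITER, "\\" + DELIMITER)


def _split_line(line: str, delimiter: str) -> list[str]:
    if delimiter == DELIMITER:
        # regex split keeps escaped delimiters inside fields
        out, buf, i, n = [], [], 0, len(line)
        while i < n:
            ch = line[i]
            if ch == "\\" and i + 1 < n:
                buf.append(line[i : i + 2])
                i += 2
            elif ch == delimiter:
                out.append(_unescape("".join(buf)))
                buf = []
                i += 1
            else:
                buf.append(ch)
                i += 1
        out.append(_unescape("".join(buf)))
        return out
    return line.split(delimiter)


def read_table(
    path: Union[str, Path],
    schema: Union[TableSchema, str],
    *,
    delimiter: str = DELIMITER,
) -> tuple[pd.DataFrame, ParseReport]:
    """Read one FAERS-dialect table.

    Parameters
    ----------
    path
        Text file with a header line naming at least the schema's required
        columns (case-insensitive) and one ``$``-delimited record per line.
    schema
        Which table this is: DEMO, DRUG, REAC or OUTC.
    delimiter
        Field separator; ``$`` for real FAERS extracts, configurable for
        fixtures.

    Returns
    -------
    (frame, report)
        ``frame`` has lower-case column names, string dtype, with empty
        fields as ``pd.NA``.  DEMO frames gain a boolean ``fda_dt_valid``
        column (YYYYMMDD calendar-date check; invalid or missing dates are
        kept, flagged, and treated as earliest by deduplication).
        ``report`` is the :class:`ParseReport` for the call.

    Raises
    ------
    ValueError
        If a required column is absent from the header.
    FileNotFoundError
        If ``path`` does not exist.
    """
    schema = TableSchema(schema)
    path = Path(path)
    report = ParseReport(path=str(path), schema=schema)

    with open(path, "r", encoding="utf-8", newline="") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file, no header line")

    header = [h.strip().lower() for h in _split_line(lines[0], delimiter)]
    required = REQUIRED_COLUMNS[schema]
    for col in required:
        if col not in header:
            raise ValueError(f"{path}: required column {col.upper()!r} missing from header")
    wanted = list(required) + [c for c in OPTIONAL_COLUMNS[schema] if c in header]
    idx = {c: header.index(c) for c in wanted}
    ncols = len(header)

    records: list[list[object]] = []
    for line in lines[1:]:
        if line == "":
            continue
        fields = _split_line(line, delimiter)
        if len(fields) > ncols:
            report.rows_skipped += 1
            continue
        if len(fields) < ncols:
            report.rows_incomplete += 1
            fields = fields + [""] * (ncols - len(fields))
        records.append([fields[idx[c]] for c in wanted])
        report.rows_read += 1

    frame = pd.DataFrame(records, columns=wanted, dtype="string")
    if frame.empty:
        frame = pd.DataFrame({c: pd.Series([], dtype="string") for c in wanted})
    frame = frame.apply(lambda s: s.str.strip())
    frame = frame.mask(frame == "", pd.NA)

    if schema is TableSchema.DEMO:
        valid = _valid_yyyymmdd(frame["fda_dt"])
        report.bad_dates = int((~valid & frame["fda_dt"].notna()).sum())
        frame["fda_dt_valid"] = valid
    return frame, report


def _valid_yyyymmdd(s: pd.Series) -> pd.Series:
    """True where the string parses as a YYYYMMDD calendar date."""
    parsed = pd.to_datetime(s, format="%Y%m%d", errors="coerce")
    return parsed.notna()


def write_table(
    frame: Union[pd.DataFrame, Sequence[Mapping[str, object]]],
    path: Union[str, Path],
    schema: Union[TableSchema, str],
    *,
    delimiter: str = DELIMITER,
) -> Path:
    """Write rows in the FAERS ASCII dialect so :func:`read_table` round-trips.

    Columns written are the schema's required columns plus any optional
    columns present.  ``None``/NA values become empty fields.  Literal
    delimiters and backslashes inside values are escaped.
    """
    schema = TableSchema(schema)
    path = Path(path)
    required = REQUIRED_COLUMNS[schema]
    if not isinstance(frame, pd.DataFrame):
        frame = pd.DataFrame(list(frame), columns=None if frame else list(required))
    frame = frame.rename(columns=str.lower)
    for col in required:
        if col not in frame.columns:
            raise ValueError(f"cannot write {schema.value}: column {col.upper()!r} missing")
    cols = list(required) + [c for c in OPTIONAL_COLUMNS[schema] if c in frame.columns]

    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(delimiter.join(c.upper() for c in cols) + "\n")
        if len(frame):
            block = frame[cols].astype(object).to_numpy()
            esc = delimiter == DELIMITER
            for row in block:
                vals = []
                for v in row:
                    if v is None or (isinstance(v, float) and np.isnan(v)) or v is pd.NA:
                        vals.append("")
                    else:
                        s = str(v)
                        vals.append(_escape(s) if esc else s)
                fh.write(delimiter.join(vals) + "\n")
    return path


def read_pt_soc_map(path: Union[str, Path]) -> dict[str, str]:
    """Read a two-column tab-delimited PT -> SOC dictionary.

    PT matching downstream is case-insensitive, so keys are lower-cased.
    Lines starting with ``#`` and blank lines are ignored.
    """
    mapping: dict[str, str] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"PT->SOC dictionary line is not two tab-separated fields: {line!r}")
        pt, soc = parts[0].strip(), parts[1].strip()
        mapping[pt.lower()] = soc
    return mapping


def write_pt_soc_map(mapping: Mapping[str, str], path: Union[str, Path]) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for pt, soc in mapping.items():
            fh.write(f"{pt}\t{soc}\n")
    return path
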