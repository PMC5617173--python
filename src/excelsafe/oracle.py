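"""Predict what spreadsheet text import does to a field.

This is the ground truth the escaper is tested against: given a raw field,
:func:`predict_conversion` models the import pipeline — formula-quoted
strings survive verbatim, a leading apostrophe is stripped, leading ``=`` or
sign runs become formulas, numbers are re-rendered (leading zeroes dropped,
exponents expanded, precision capped at 15 significant digits), and
date-like / time-like text is re-rendered as a date or time. A field whose
stored text differs from its input is *lossy* — silently corrupted.

The numeric precision model follows spreadsheet behaviour: decimal digits
past the 15th significant digit are irrecoverably zeroed (truncation, not
rounding — 1234567890123456789 is stored as 1234567890123450000).

``stored_text`` for large integers is the full zero-filled integer, not the
scientific-notation display string; date predictions carry no year.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field as dc_field
from decimal import Decimal
from typing import Iterable, Optional, Sequence

from .rules import match_date_time, parse_number

__all__ = [
    "ConversionPrediction",
    "AuditRecord",
    "AuditReport",
    "fifteen_digit_store",
    "predict_conversion",
    "audit_table",
    "workbook_column",
]

PREDICTION_KINDS = frozenset(
    {"unchanged", "number", "date", "time", "formula", "quote_stripped"}
)

_WRAPPED_RE = re.compile(r'^="(.*)"$', re.DOTALL)
# A sign run must be followed by at least one non-sign character; a field of
# bare signs ("++") is imported unchanged.
_SIGN_RUN_RE = re.compile(r"^([+-]+)([^+-].*)$", re.DOTALL)


@dataclass(frozen=True)
class ConversionPrediction:
    kind: str
    stored_text: str
    lossy: bool

    def __post_init__(self) -> None:
        if self.kind not in PREDICTION_KINDS:
            raise ValueError(f"unknown prediction kind: {self.kind!r}")


def fifteen_digit_store(int_text: str) -> str:
    """Zero out decimal digits beyond the 15th significant digit.

    Models how a spreadsheet's binary-double cell loses precision on long
    integers: the digit string is truncated at 15 significant digits and
    zero-filled back to its original length. Input must be digits only.
    """
    if not int_text.isdigit():
        raise ValueError("fifteen_digit_store expects an unsigned digit string")
    significant = int_text.lstrip("0")
    if len(significant) <= 15:
        return int_text
    prefix = int_text[: len(int_text) - len(significant)]
    return prefix + significant[:15] + "0" * (len(significant) - 15)


def _render_number(text: str) -> str:
    """Stored text for a field the import pipeline treats as numeric."""
    value = Decimal(text)
    integral = value.to_integral_value()
    if value == integral:
        magnitude = fifteen_digit_store(str(abs(int(integral))))
        return ("-" if integral < 0 else "") + magnitude
    # Fractional values: shortest round-trip rendering of the double.
    rendered = repr(float(text))
    if rendered.endswith(".0"):
        rendered = rendered[:-2]
    return rendered


def predict_conversion(field: str) -> ConversionPrediction:
    """Model the auto-conversion a spreadsheet applies on text import."""
    m = _WRAPPED_RE.match(field)
    if m is not None:
        body = m.group(1).replace('""', '"')
        return ConversionPrediction("unchanged", body, False)
    if field.startswith("'"):
        return ConversionPrediction("quote_stripped", field[1:], True)
    if parse_number(field) is not None:
        stored = _render_number(field)
        return ConversionPrediction("number", stored, stored != field)
    if field.startswith("="):
        body = field[1:]
        if body and parse_number(body) is not None:
            return ConversionPrediction("number", _render_number(body), True)
        return ConversionPrediction("formula", "#NAME?", True)
    m = _SIGN_RUN_RE.match(field)
    if m is not None:
        signs, body = m.groups()
        if parse_number(body) is not None:
            negative = signs.count("-") % 2 == 1
            stored = _render_number(("-" if negative else "") + body)
            return ConversionPrediction("number", stored, True)
        return ConversionPrediction("formula", "#NAME?", True)
    found = match_date_time(field)
    if found is not None:
        if found.kind == "date_like":
            stored = f"{found.day}-{found.month_abbr}"
            return ConversionPrediction("date", stored, stored != field)
        hour12 = found.hour % 12 or 12
        suffix = "AM" if found.hour < 12 else "PM"
        stored = f"{hour12}:{found.minute:02d} {suffix}"
        return ConversionPrediction("time", stored, stored != field)
    return ConversionPrediction("unchanged", field, False)


@dataclass(frozen=True)
class AuditRecord:
    row: int
    column: int
    text: str
    stored_text: str
    kind: str


@dataclass
class AuditReport:
    """Aggregate corruption audit over a table of raw fields.

    ``by_kind`` counts only lossy fields, keyed by prediction kind, so
    ``corrupted == sum(by_kind.values())``.
    """

    total: int = 0
    corrupted: int = 0
    by_kind: Counter = dc_field(default_factory=Counter)
    records: list[AuditRecord] = dc_field(default_factory=list)


def audit_table(
    rows: Iterable[Sequence[str]],
    columns: Optional[Iterable[int]] = None,
) -> AuditReport:
    """Predict conversions for every (selected) field and tally the damage.

    *columns* optionally restricts the audit to the given 0-based column
    indices; absent columns in short rows are skipped silently.
    """
    wanted = None if columns is None else sorted(set(columns))
    report = AuditReport()
    for r, row in enumerate(rows):
        indices = range(len(row)) if wanted is None else [c for c in wanted if c < len(row)]
        for c in indices:
            text = row[c]
            prediction = predict_conversion(text)
            report.total += 1
            if prediction.lossy:
                report.corrupted += 1
                report.by_kind[prediction.kind] += 1
                report.records.append(
                    AuditRecord(r, c, text, prediction.stored_text, prediction.kind)
                )
    return report


def workbook_column(
    path: str,
    sheet: Optional[str] = None,
    column: int = 0,
    *,
    skip_header: bool = True,
) -> list[str]:
    """Read one column of an Office Open XML worksheet as text fields.

    Convenience for auditing symbol lists distributed as workbooks. Cells
    are stringified; ``None`` cells end the scan of trailing padding but
    interior blanks become empty strings.
    """
    import openpyxl

    book = openpyxl.load_workbook(path, read_only=True, data_only=True)
    try:
        sheet_obj = book[sheet] if sheet is not None else book.worksheets[0]
        values: list[str] = []
        for i, row in enumerate(sheet_obj.iter_rows(min_col=column + 1, max_col=column + 1)):
            if skip_header and i == 0:
                continue
            cell = row[0].value
            values.append("" if cell is None else str(cell))
        while values and values[-1] == "":
            values.pop()
        return values
    finally:
        book.close()

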