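"""Bundled validation data and synthetic gene-table generation.

``validation_table`` is the package's executable contract: a deterministic
list of fields, each annotated with the rule tag the decision engine must
report and the conversion the import oracle must predict. It covers every
rule tag several times over, the canonical corruption examples (date-coerced
symbols, scientific-notation accessions, dropped leading zeroes, formula
coercion, long-integer precision loss), and the five deliberately unescaped
strings that could be genuine scientific notation.

``synth_gene_table`` produces seeded symbol tables with truth labels for
recall testing at arbitrary scale.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

__all__ = [
    "ValidationRow",
    "validation_table",
    "SynthTable",
    "synth_gene_table",
    "EXCLUDED_STRINGS",
]

#: Deliberately unescaped despite being predicted lossy: single-digit
#: mantissa scientific notation could be a genuine number in other contexts.
EXCLUDED_STRINGS = ("2E4", "2E6", "2E12", "3E2", "3e46")


@dataclass(frozen=True)
class ValidationRow:
    """One contract row: input field, expected decision, expected conversion."""

    text: str
    tag: str          # expected EscapeDecision.rule under `config`
    kind: str         # expected ConversionPrediction.kind for the raw text
    stored: str       # expected ConversionPrediction.stored_text
    config: str = "default"   # "default" or "paranoid"
    excluded: bool = False    # passed by the rules although predicted lossy

    @property
    def lossy(self) -> bool:
        return self.stored != self.text


def validation_table() -> list[ValidationRow]:
    """The deterministic should-escape / must-not-escape contract table."""
    R = ValidationRow
    rows = [
        # Canonical corruption examples: unescaped import mangles these.
        R("00123456", "leading_zero", "number", "123456"),
        R("1234567890123456789", "long_integer", "number", "1234567890123450000"),
        R("2610100E13", "sci_mantissa", "number", "26101000000000000000"),
        R("SEPT7", "date_like", "date", "7-Sep"),
        R("1/3", "date_like", "date", "3-Jan"),
        R("1 A", "time_like", "time", "1:00 AM"),
        R("++ stain intensity", "leading_plusminus", "formula", "#NAME?"),
        # Deliberately unescaped despite lossy predictions.
        R("2E4", "none", "number", "20000", excluded=True),
        R("2E6", "none", "number", "2000000", excluded=True),
        R("2E12", "none", "number", "2000000000000", excluded=True),
        R("3E2", "none", "number", "300", excluded=True),
        R("3e46", "none", "number", "3" + "0" * 46, excluded=True),
        # Safe text: neither escaped nor predicted lossy.
        R("TP53", "none", "unchanged", "TP53"),
        R("BRCA1", "none", "unchanged", "BRCA1"),
        R("SEPTIN7", "none", "unchanged", "SEPTIN7"),
        R("MARCHF1", "none", "unchanged", "MARCHF1"),
        R("gene list", "none", "unchanged", "gene list"),
        R("11A9", "none", "unchanged", "11A9"),
        R("", "none", "unchanged", ""),
        R("1,234", "none", "unchanged", "1,234"),
        R('ab"c', "none", "unchanged", 'ab"c'),
        R("++", "none", "unchanged", "++"),
        # Safe numbers: stored exactly as written.
        R("123456", "none", "number", "123456"),
        R("-1", "none", "number", "-1"),
        R("1.5", "none", "number", "1.5"),
        # Leading zeroes.
        R("0123", "leading_zero", "number", "123"),
        R("007", "leading_zero", "number", "7"),
        R("00", "leading_zero", "number", "0"),
        R("012.5", "leading_zero", "number", "12.5"),
        R("0001e2", "leading_zero", "number", "100"),
        # Scientific notation with >= 2 mantissa digits.
        R("11E9", "sci_mantissa", "number", "11000000000"),
        R("12E3", "sci_mantissa", "number", "12000"),
        R("99E99", "sci_mantissa", "number", "99" + "0" * 99),
        R("10e2", "sci_mantissa", "number", "1000"),
        R("123.4E2", "sci_mantissa", "number", "12340"),
        # More than 11 digits before the decimal point.
        R(
            "52070900777217100409406332354780",
            "long_integer",
            "number",
            "52070900777217100000000000000000",
        ),
        R("123456789012", "long_integer", "number", "123456789012"),
        R("999999999999999999", "long_integer", "number", "999999999999999000"),
        R("9999999999999999", "long_integer", "number", "9999999999999990"),
        R("123456789012.5", "long_integer", "number", "123456789012.5"),
        # Leading single quote (stripped on import).
        R("'escape me", "leading_quote", "quote_stripped", "escape me"),
        R("'123", "leading_quote", "quote_stripped", "123"),
        R("''double", "leading_quote", "quote_stripped", "'double"),
        R("'", "leading_quote", "quote_stripped", ""),
        R("'SEPT7", "leading_quote", "quote_stripped", "SEPT7"),
        # Leading equals sign (treated as a formula).
        R("=SUM(A1)", "leading_equals", "formula", "#NAME?"),
        R("=A1+B1", "leading_equals", "formula", "#NAME?"),
        R("=123", "leading_equals", "number", "123"),
        R("=", "leading_equals", "formula", "#NAME?"),
        R("=hello", "leading_equals", "formula", "#NAME?"),
        # Leading +/- run followed by other text.
        R("+- mixed", "leading_plusminus", "formula", "#NAME?"),
        R("-abc", "leading_plusminus", "formula", "#NAME?"),
        R("+++4", "leading_plusminus", "number", "4"),
        R("- note", "leading_plusminus", "formula", "#NAME?"),
        R("--2", "leading_plusminus", "number", "2"),
        # Date-like text.
        R("MARCH1", "date_like", "date", "1-Mar"),
        R("DEC1", "date_like", "date", "1-Dec"),
        R("SEP15", "date_like", "date", "15-Sep"),
        R("7-Sep", "date_like", "date", "7-Sep"),
        R("Oct 31", "date_like", "date", "31-Oct"),
        R("3/4/2017", "date_like", "date", "4-Mar"),
        R("1-jan", "date_like", "date", "1-Jan"),
        R("APR-1", "date_like", "date", "1-Apr"),
        # Time-like text.
        R("12:30", "time_like", "time", "12:30 PM"),
        R("23:59", "time_like", "time", "11:59 PM"),
        R("2 P", "time_like", "time", "2:00 PM"),
        R("5A", "time_like", "time", "5:00 AM"),
        R("1:02:03", "time_like", "time", "1:02 AM"),
        R("9:05 am", "time_like", "time", "9:05 AM"),
        # Paranoid mode: every non-number is escaped, numbers still pass.
        R("TP53", "paranoid", "unchanged", "TP53", config="paranoid"),
        R("hello world", "paranoid", "unchanged", "hello world", config="paranoid"),
        R("A1CF", "paranoid", "unchanged", "A1CF", config="paranoid"),
        R("NAT1", "paranoid", "unchanged", "NAT1", config="paranoid"),
        R("abc def", "paranoid", "unchanged", "abc def", config="paranoid"),
        R("123456", "none", "number", "123456", config="paranoid"),
    ]
    return rows


# --------------------------------------------------------------------------
# Synthetic gene tables

_SAFE_SYMBOLS = (
    "TP53", "BRCA1", "BRCA2", "EGFR", "KRAS", "NRAS", "MYC", "PTEN",
    "GAPDH", "ACTB", "SEPTIN7", "SEPTIN9", "MARCHF8", "CENPA", "FOXP2",
    "SOX9", "PAX6", "NANOG", "POU5F1", "CDKN2A", "ALDH1A1", "HNF4A",
    "TGFB1", "CTNNB1", "NOTCH1",
)

_VULNERABLE_FAMILIES = (
    "septin_date",
    "march_date",
    "dec_date",
    "riken_sci",
    "zero_padded",
    "long_barcode",
)


@dataclass
class SynthTable:
    """A one-column symbol table with per-field truth labels.

    Labels are ``safe``, ``vulnerable`` (must be escaped and is predicted
    lossy), or ``excluded`` (predicted lossy but deliberately not escaped).
    """

    fields: list[str]
    labels: list[str]

    def to_tsv(self) -> str:
        return "".join(f + "\n" for f in self.fields)

    def labels_to_tsv(self) -> str:
        return "".join(f"{f}\t{l}\n" for f, l in zip(self.fields, self.labels))

    def write(self, table_path: str | Path, labels_path: str | Path) -> None:
        Path(table_path).write_text(self.to_tsv(), encoding="utf-8")
        Path(labels_path).write_text(self.labels_to_tsv(), encoding="utf-8")


def _vulnerable_field(rng: random.Random) -> str:
    family = rng.choice(_VULNERABLE_FAMILIES)
    if family == "septin_date":
        return f"SEPT{rng.randint(1, 14)}"
    if family == "march_date":
        return f"MARCH{rng.randint(1, 11)}"
    if family == "dec_date":
        return f"DEC{rng.randint(1, 2)}"
    if family == "riken_sci":
        return f"{rng.randint(1, 9)}{rng.randint(0, 999999):06d}E{rng.randint(0, 99):02d}"
    if family == "zero_padded":
        return "0" * rng.randint(1, 3) + str(rng.randint(1, 99999))
    # long_barcode: 16-30 digits, with a nonzero digit beyond the 15th so
    # precision truncation is guaranteed to corrupt it.
    length = rng.randint(16, 30)
    digits = [str(rng.randint(1, 9))]
    digits += [str(rng.randint(0, 9)) for _ in range(length - 2)]
    digits.insert(15, str(rng.randint(1, 9)))
    return "".join(digits[:length])


def synth_gene_table(n_rows: int, corruption_rate: float, seed: int) -> SynthTable:
    """Generate a seeded symbol table; *corruption_rate* of fields are drawn
    from families known to be corrupted by spreadsheet import."""
    if not 0.0 <= corruption_rate <= 1.0:
        raise ValueError("corruption_rate must be within [0, 1]")
    if n_rows < 0:
        raise ValueError("n_rows must be non-negative")
    rng = random.Random(seed)
    fields: list[str] = []
    labels: list[str] = []
    for _ in range(n_rows):
        if rng.random() < corruption_rate:
            fields.append(_vulnerable_field(rng))
            labels.append("vulnerable")
        elif rng.random() < 0.05:
            fields.append(rng.choice(EXCLUDED_STRINGS))
            labels.append("excluded")
        else:
            fields.append(rng.choice(_SAFE_SYMBOLS))
            labels.append("safe")
    return SynthTable(fields, labels)
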