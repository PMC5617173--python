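"""Escape-decision logic for cleaned fields.

A field is examined as a number first. Numbers are escaped only for the
numeric hazards (leading zeroes, risky scientific notation, very long
integers). Everything else is checked for the textual hazards: a leading
single quote, a leading equals sign, a leading run of plus/minus signs
followed by other text, and date- or time-likeness. Paranoid mode escapes
every non-number outright.

The date/time grammar lives here and is shared with
:mod:`excelsafe.oracle`, so what we escape and what we predict a
spreadsheet will mangle can only diverge where that is a deliberate,
documented choice.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

__all__ = [
    "RuleConfig",
    "NumberParts",
    "EscapeDecision",
    "DateTimeMatch",
    "RULE_TAGS",
    "parse_number",
    "number_needs_escape",
    "match_date_time",
    "looks_like_date_or_time",
    "decide_escape",
]

#: Every tag an :class:`EscapeDecision` may carry.
RULE_TAGS = frozenset(
    {
        "none",
        "leading_zero",
        "sci_mantissa",
        "long_integer",
        "leading_quote",
        "leading_equals",
        "leading_plusminus",
        "date_like",
        "time_like",
        "paranoid",
    }
)


@dataclass(frozen=True)
class RuleConfig:
    """The four behaviour flags controlling which rule classes are active."""

    escape_dates: bool = True
    escape_sci: bool = True
    escape_zeroes: bool = True
    paranoid: bool = False


@dataclass(frozen=True)
class NumberParts:
    """Decomposition of a numeric field; ``reassemble`` is lossless."""

    sign: Optional[str]
    int_digits: str
    point: bool
    frac_digits: str
    exp_char: Optional[str]
    exp_sign: Optional[str]
    exp_digits: Optional[str]

    @property
    def mantissa_int_len(self) -> int:
        """Number of digits before the decimal point."""
        return len(self.int_digits)

    @property
    def has_exponent(self) -> bool:
        return self.exp_digits is not None

    def reassemble(self) -> str:
        out = (self.sign or "") + self.int_digits
        if self.point:
            out += "." + self.frac_digits
        if self.exp_char is not None:
            out += self.exp_char + (self.exp_sign or "") + (self.exp_digits or "")
        return out


@dataclass(frozen=True)
class EscapeDecision:
    escape: bool
    rule: str

    def __post_init__(self) -> None:
        if self.rule not in RULE_TAGS:
            raise ValueError(f"unknown rule tag: {self.rule!r}")
        if self.escape == (self.rule == "none"):
            raise ValueError("escape flag inconsistent with rule tag")


_PASS = EscapeDecision(False, "none")

# Optional sign; digits with an optional single decimal point (digits on at
# least one side); optional exponent with optional sign and >=1 digit.
_NUMBER_RE = re.compile(
    r"""^([+-])?
        (?:(\d+)(?:\.(\d*))?|\.(\d+))
        (?:([eE])([+-])?(\d+))?$""",
    re.VERBOSE,
)


def parse_number(field: str) -> Optional[NumberParts]:
    """Parse a cleaned field as a number, or return ``None``."""
    m = _NUMBER_RE.match(field)
    if m is None:
        return None
    sign, ints, frac_after_int, frac_only, exp_char, exp_sign, exp_digits = m.groups()
    if frac_only is not None:
        int_digits, point, frac = "", True, frac_only
    else:
        int_digits = ints
        point = frac_after_int is not None
        frac = frac_after_int or ""
    return NumberParts(sign, int_digits, point, frac, exp_char, exp_sign, exp_digits)


def number_needs_escape(parts: NumberParts, config: RuleConfig) -> EscapeDecision:
    """Numeric branch: leading zeroes, then the two scientific-notation rules.

    The first matching rule wins. ``long_integer`` fires on more than 11
    digits before the decimal point whether or not a fractional part is
    present.
    """
    if (
        config.escape_zeroes
        and len(parts.int_digits) > 1
        and parts.int_digits[0] == "0"
    ):
        return EscapeDecision(True, "leading_zero")
    if config.escape_sci and parts.has_exponent and parts.mantissa_int_len >= 2:
        return EscapeDecision(True, "sci_mantissa")
    if config.escape_sci and parts.mantissa_int_len > 11:
        return EscapeDecision(True, "long_integer")
    return _PASS


# --------------------------------------------------------------------------
# Date / time grammar
#
# A spreadsheet's real grammar is locale- and version-dependent, so this one
# is deliberately a little broader: over-escaping is harmless, silent
# corruption is not. A month token is a 3+ letter prefix of an English month
# name (SEP, SEPT, SEPTE, ... all match; SEPTI does not, which is what keeps
# SEPTIN7 safe).

_MONTH_NAMES = (
    "january",
    "february",
    "march",
    "april",
    "may",
    "june",
    "july",
    "august",
    "september",
    "october",
    "november",
    "december",
)

_MONTH_ABBR = (
    "Jan",
    "Feb",
    "Mar",
    "Apr",
    "May",
    "Jun",
    "Jul",
    "Aug",
    "Sep",
    "Oct",
    "Nov",
    "Dec",
)

_MONTH_BY_PREFIX: dict[str, int] = {}
for _i, _name in enumerate(_MONTH_NAMES, start=1):
    for _ln in range(3, len(_name) + 1):
        _MONTH_BY_PREFIX[_name[:_ln]] = _i

# Longest prefixes first so the regex engine prefers the maximal month token.
_MONTH_ALT = "|".join(sorted(_MONTH_BY_PREFIX, key=len, reverse=True))

_SEP = r"[ \-/.]"

_MONTH_DAY_RE = re.compile(
    rf"^(?P<mon>{_MONTH_ALT})\.?{_SEP}?(?P<day>\d{{1,2}})"
    rf"(?:{_SEP}(?P<year>\d{{2}}|\d{{4}}))?$",
    re.IGNORECASE,
)
_DAY_MONTH_RE = re.compile(
    rf"^(?P<day>\d{{1,2}}){_SEP}?(?P<mon>{_MONTH_ALT})"
    rf"(?:{_SEP}(?P<year>\d{{2}}|\d{{4}}))?$",
    re.IGNORECASE,
)
_NUMERIC_DATE_RE = re.compile(
    r"^(?P<a>\d{1,2})(?P<sep>[/-])(?P<b>\d{1,2})(?:(?P=sep)(?P<c>\d{1,4}))?$"
)
_ISO_DATE_RE = re.compile(r"^(?P<y>\d{4})(?P<sep>[/-])(?P<m>\d{1,2})(?P=sep)(?P<d>\d{1,2})$")

_CLOCK_RE = re.compile(
    r"^(?P<h>\d{1,2}):(?P<m>\d{1,2})(?::(?P<s>\d{1,2}))?"
    r"(?:\s*(?P<ap>[AaPp])[Mm]?)?$"
)
_HOUR_AP_RE = re.compile(r"^(?P<h>\d{1,2})\s*(?P<ap>[AaPp])[Mm]?$")


@dataclass(frozen=True)
class DateTimeMatch:
    """A date or time interpretation of a field, used for oracle rendering."""

    kind: str  # "date_like" or "time_like"
    month: int = 0
    day: int = 0
    hour: int = 0
    minute: int = 0

    @property
    def month_abbr(self) -> str:
        return _MONTH_ABBR[self.month - 1]


def _month_day(mon_token: str, day_text: str) -> Optional[DateTimeMatch]:
    day = int(day_text)
    if not 1 <= day <= 31:
        return None
    month = _MONTH_BY_PREFIX[mon_token.lower()]
    return DateTimeMatch("date_like", month=month, day=day)


def _numeric_month_day(a: int, b: int) -> Optional[DateTimeMatch]:
    # Month-first wins when ambiguous (US-style import).
    if 1 <= a <= 12 and 1 <= b <= 31:
        return DateTimeMatch("date_like", month=a, day=b)
    if 1 <= b <= 12 and 1 <= a <= 31:
        return DateTimeMatch("date_like", month=b, day=a)
    return None


def match_date_time(field: str) -> Optional[DateTimeMatch]:
    """Match the shared date/time grammar, returning rendering details.

    Callers must have ruled the field out as a number first; pure numbers
    never reach the grammar.
    """
    m = _MONTH_DAY_RE.match(field) or _DAY_MONTH_RE.match(field)
    if m is not None:
        found = _month_day(m.group("mon"), m.group("day"))
        if found is not None:
            return found
    m = _NUMERIC_DATE_RE.match(field)
    if m is not None:
        found = _numeric_month_day(int(m.group("a")), int(m.group("b")))
        if found is not None:
            return found
    m = _ISO_DATE_RE.match(field)
    if m is not None:
        mon, day = int(m.group("m")), int(m.group("d"))
        if 1 <= mon <= 12 and 1 <= day <= 31:
            return DateTimeMatch("date_like", month=mon, day=day)
    m = _CLOCK_RE.match(field)
    if m is not None:
        hour, minute = int(m.group("h")), int(m.group("m"))
        second = int(m.group("s")) if m.group("s") else 0
        ap = m.group("ap")
        if minute <= 59 and second <= 59:
            if ap is not None:
                if 1 <= hour <= 12:
                    if ap.lower() == "p" and hour != 12:
                        hour += 12
                    elif ap.lower() == "a" and hour == 12:
                        hour = 0
                    return DateTimeMatch("time_like", hour=hour, minute=minute)
            elif hour <= 23:
                return DateTimeMatch("time_like", hour=hour, minute=minute)
    m = _HOUR_AP_RE.match(field)
    if m is not None:
        hour = int(m.group("h"))
        if 1 <= hour <= 12:
            if m.group("ap").lower() == "p" and hour != 12:
                hour += 12
            elif m.group("ap").lower() == "a" and hour == 12:
                hour = 0
            return DateTimeMatch("time_like", hour=hour, minute=0)
    return None


def looks_like_date_or_time(field: str) -> str:
    """Classify a clean non-number field as date_like, time_like, or none."""
    found = match_date_time(field)
    return found.kind if found is not None else "none"


_LEADING_SIGNS_RE = re.compile(r"^[+-]+[^+-]")


def decide_escape(field: str, config: RuleConfig = RuleConfig()) -> EscapeDecision:
    """Decide whether a clean field must be escaped and which rule fired.

    Empty fields always pass. Numbers go through the numeric branch only;
    non-numbers are escaped wholesale under paranoid mode, otherwise checked
    for leading quote, leading equals, leading sign run, and (when the dates
    flag is on) date/time-likeness, in that order.
    """
    if field == "":
        return _PASS
    parts = parse_number(field)
    if parts is not None:
        return number_needs_escape(parts, config)
    if config.paranoid:
        return EscapeDecision(True, "paranoid")
    if field[0] == "'":
        return EscapeDecision(True, "leading_quote")
    if field[0] == "=":
        return EscapeDecision(True, "leading_equals")
    if _LEADING_SIGNS_RE.match(field):
        return EscapeDecision(True, "leading_plusminus")
    if config.escape_dates:
        tag = looks_like_date_or_time(field)
        if tag != "none":
            return EscapeDecision(True, tag)
    return _PASS
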