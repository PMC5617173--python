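"""Escape a tab-delimited document, field by field.

Each cell is cleaned to its canonical text, the rule engine decides whether
it is at risk, and at-risk cells are wrapped as a formula-quoted string
(``="..."``) which a spreadsheet imports as literal text. Row count, column
structure, and field order are preserved exactly; processing twice is
byte-identical to processing once because cleaning removes prior escaping.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field as dc_field
from typing import IO, Iterable, Iterator

from .rules import RuleConfig, decide_escape
from .textclean import BOM, clean_field

__all__ = [
    "DecodeError",
    "ProcessStats",
    "wrap_field",
    "unwrap_field",
    "process_field",
    "process_stream",
    "process_text",
    "iter_decoded_lines",
]

logger = logging.getLogger(__name__)


class DecodeError(ValueError):
    """Input bytes are not valid UTF-8; carries the 1-based line number."""

    def __init__(self, line_number: int, cause: UnicodeDecodeError):
        self.line_number = line_number
        super().__init__(f"line {line_number}: undecodable UTF-8 input ({cause})")


@dataclass
class ProcessStats:
    """Counts gathered while escaping a document."""

    lines: int = 0
    fields: int = 0
    escaped: int = 0
    by_rule: Counter = dc_field(default_factory=Counter)

    def summary(self) -> str:
        rules = ", ".join(f"{tag}={n}" for tag, n in sorted(self.by_rule.items()))
        return (
            f"{self.lines} lines, {self.fields} fields, "
            f"{self.escaped} escaped ({rules or 'none'})"
        )


def wrap_field(field: str) -> str:
    """Wrap a clean field as ``="..."`` with interior quotes doubled."""
    return '="' + field.replace('"', '""') + '"'


def unwrap_field(field: str) -> str:
    """Inverse of :func:`wrap_field`; non-wrapped fields pass through."""
    if field.startswith('="') and field.endswith('"') and len(field) >= 3:
        return field[2:-1].replace('""', '"')
    return field


def process_field(field: str, config: RuleConfig = RuleConfig()) -> str:
    """Clean one raw field, then escape it if any rule fires."""
    cleaned = clean_field(field)
    if decide_escape(cleaned, config).escape:
        return wrap_field(cleaned)
    return cleaned


def process_stream(
    lines: Iterable[str],
    output: IO[str],
    config: RuleConfig = RuleConfig(),
    *,
    newline: str = "\n",
) -> ProcessStats:
    """Escape every field of every line, writing terminated lines to *output*.

    *lines* must already be free of line terminators (see
    :func:`iter_decoded_lines` and :mod:`excelsafe.eol`). Ragged rows are
    preserved as-is with a logged warning.
    """
    stats = ProcessStats()
    expected_width: int | None = None
    for line in lines:
        raw_fields = line.split("\t")
        if expected_width is None:
            expected_width = len(raw_fields)
        elif len(raw_fields) != expected_width:
            logger.warning(
                "ragged row %d: %d fields, expected %d",
                stats.lines + 1,
                len(raw_fields),
                expected_width,
            )
        out_fields = []
        for raw in raw_fields:
            cleaned = clean_field(raw)
            decision = decide_escape(cleaned, config)
            if decision.escape:
                out_fields.append(wrap_field(cleaned))
                stats.escaped += 1
                stats.by_rule[decision.rule] += 1
            else:
                out_fields.append(cleaned)
        output.write("\t".join(out_fields) + newline)
        stats.lines += 1
        stats.fields += len(raw_fields)
    return stats


def process_text(
    text: str, config: RuleConfig = RuleConfig(), *, newline: str = "\n"
) -> tuple[str, ProcessStats]:
    """Convenience wrapper: escape a whole document held in memory."""
    import io

    lines = text.split("\n")
    # split() manufactures a trailing empty line when the text ends with \n.
    if lines and lines[-1] == "":
        lines.pop()
    sink = io.StringIO()
    stats = process_stream(lines, sink, config, newline=newline)
    return sink.getvalue(), stats


def iter_decoded_lines(data: bytes) -> Iterator[str]:
    """Decode normalized (LF-terminated) bytes line by line.

    A file-level byte order mark is stripped before the first line is
    yielded. Invalid UTF-8 raises :class:`DecodeError` naming the line.
    """
    if data.startswith(b"\xef\xbb\xbf"):
        data = data[3:]
    raw_lines = data.split(b"\n")
    if raw_lines and raw_lines[-1] == b"":
        raw_lines.pop()
    for number, raw in enumerate(raw_lines, start=1):
        try:
            text = raw.decode("utf-8")
        except UnicodeDecodeError as exc:
            raise DecodeError(number, exc) from exc
        if number == 1 and text.startswith(BOM):
            text = text[1:]
        yield text
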