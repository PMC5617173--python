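"""Field-cleaning primitives.

Raw fields arriving from exported text files frequently carry artifacts that
interfere both with pattern matching and with how a spreadsheet parses the
eventual output: UTF-8 byte order marks, enclosing or stray double quotes,
escaping left over from a previous pass through this tool, and space padding.
``clean_field`` iterates the individual removal rules to a fixpoint; the
result is the canonical text content a spreadsheet should ultimately display.

Every rule either leaves its input unchanged or strictly shortens it, so the
fixpoint loop terminates in at most ``len(field)`` passes and the fixpoint is
independent of the order the rules are applied in.
"""

from __future__ import annotations

import re

__all__ = [
    "BOM",
    "strip_bom",
    "strip_prior_escape",
    "strip_quotes",
    "strip_pad",
    "clean_field",
]

#: The Unicode byte order mark as it appears after UTF-8 decoding.
BOM = "\ufeff"

# An entire field of the form ="..." (the escaping this package emits).
_PRIOR_ESCAPE_RE = re.compile(r'^="(.*)"$', re.DOTALL)


def strip_bom(field: str) -> str:
    """Remove a single leading byte order mark; interior marks are kept."""
    if field.startswith(BOM):
        return field[1:]
    return field


def strip_prior_escape(field: str) -> str:
    """Unwrap one layer of ``="..."`` escaping, undoubling interior quotes.

    Fields that are not exactly of that shape (e.g. ``=SUM(A1)``) are
    returned unchanged. Nested layers are removed one per call; the
    fixpoint loop in :func:`clean_field` finishes the job.
    """
    m = _PRIOR_ESCAPE_RE.match(field)
    if m is None:
        return field
    return m.group(1).replace('""', '"')


def strip_quotes(field: str) -> str:
    """Remove a matching pair of enclosing double quotes, else a leading one.

    A lone ``"`` counts as a leading quote and becomes the empty string.
    Interior quotes are never touched.
    """
    if len(field) >= 2 and field[0] == '"' and field[-1] == '"':
        return field[1:-1]
    if field.startswith('"'):
        return field[1:]
    return field


def strip_pad(field: str) -> str:
    """Remove leading and trailing U+0020 spaces (only that code point)."""
    return field.strip(" ")


_RULES = (strip_bom, strip_prior_escape, strip_quotes, strip_pad)


def clean_field(field: str) -> str:
    """Apply all cleaning rules repeatedly until none changes the field.

    The result is idempotent: ``clean_field(clean_field(f)) == clean_field(f)``.
    The empty string is a valid clean field.
    """
    current = field
    while True:
        previous = current
        for rule in _RULES:
            current = rule(current)
        if current == previous:
            return current
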