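"""Line-terminator normalization.

Classic-Mac CR-only terminators (still emitted by some spreadsheet exports),
CRLF, and LF are all rewritten to a single target convention before the
tokenizer sees the data. Works on whole byte strings or as a streaming pipe
filter; a CR split across a chunk boundary is handled correctly, and a final
line without a terminator stays without one.
"""

from __future__ import annotations

import re
from typing import BinaryIO

__all__ = ["TERMINATORS", "normalize_eol", "normalize_eol_stream"]

TERMINATORS = {"lf": b"\n", "crlf": b"\r\n"}

_EOL_RE = re.compile(rb"\r\n|\r|\n")


def _target_bytes(target: str) -> bytes:
    try:
        return TERMINATORS[target.lower()]
    except KeyError:
        raise ValueError(f"unknown line terminator target: {target!r}") from None


def normalize_eol(data: bytes, target: str = "lf") -> bytes:
    """Rewrite every CRLF / CR / LF terminator in *data* to *target*."""
    return _EOL_RE.sub(_target_bytes(target), data)


def normalize_eol_stream(
    source: BinaryIO,
    sink: BinaryIO,
    target: str = "lf",
    *,
    chunk_size: int = 1 << 16,
) -> int:
    """Stream *source* to *sink*, normalizing terminators; returns line count.

    A trailing CR is held back between chunks so CRLF pairs straddling a
    boundary collapse to one terminator.
    """
    eol = _target_bytes(target)
    pending = b""
    lines = 0
    while True:
        chunk = source.read(chunk_size)
        if not chunk:
            break
        buffer = pending + chunk
        if buffer.endswith(b"\r"):
            pending, buffer = b"\r", buffer[:-1]
        else:
            pending = b""
        lines += len(_EOL_RE.findall(buffer))
        sink.write(_EOL_RE.sub(eol, buffer))
    if pending:
        lines += 1
        sink.write(eol)
    return lines
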