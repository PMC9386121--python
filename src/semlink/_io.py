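"""Small input helpers shared by the flat-file parsers."""

from __future__ import annotations

import os
from typing import IO, Iterable


def read_lines(source: str | os.PathLike | IO[str]) -> list[str]:
    """Return the lines of ``source``.

    ``source`` may be a file-like object, a filesystem path, or — as a
    convenience for inline fixtures — a string that contains a newline,
    which is treated as raw file content.
    """
    if hasattr(source, "read"):
        return source.read().splitlines()
    if isinstance(source, os.PathLike):
        with open(source, "r", encoding="utf-8") as handle:
            return handle.read().splitlines()
    if isinstance(source, str):
        if "\n" in source:
            return source.splitlines()
        with open(source, "r", encoding="utf-8") as handle:
            return handle.read().splitlines()
    raise TypeError(f"cannot read from {type(source).__name__}")
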