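"""Small shared helpers."""

from __future__ import annotations

import gzip
import io
from pathlib import Path


def deterministic_gzip_writer(path: str | Path) -> gzip.GzipFile:
    """Binary gzip writer with mtime=0 and no embedded filename, so
    identical content always yields byte-identical files."""
    raw = open(path, "wb")
    gz = gzip.GzipFile(filename="", mode="wb", fileobj=raw, mtime=0)
    gz.myfileobj = raw  # have close() also close the underlying file
    return gz


def open_text(path: str | Path, mode: str):
    """Text open with transparent gzip (deterministic on write)."""
    path = Path(path)
    gzipped = path.suffix == ".gz"
    if "r" in mode:
        return gzip.open(path, "rt") if gzipped else open(path, "r")
    if gzipped:
        return io.TextIOWrapper(deterministic_gzip_writer(path))
    return open(path, mode)
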