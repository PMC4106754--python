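"""Shared I/O plumbing: transparent gzip, float formatting, write reports."""

from __future__ import annotations

import gzip
import io
import os
from contextlib import contextmanager
from dataclasses import dataclass, field


def _is_path(obj) -> bool:
    return isinstance(obj, (str, bytes, os.PathLike))


@contextmanager
def open_source(source, binary: bool = False):
    """Yield a readable file object for a path (``.gz`` transparent) or pass
    through an already-open file object unchanged."""
    if _is_path(source):
        name = os.fspath(source)
        opener = gzip.open if name.endswith(".gz") else open
        mode = "rb" if binary else "rt"
        with opener(name, mode) as fh:
            yield fh
    else:
        yield source


@contextmanager
def open_sink(sink, binary: bool = False):
    """Yield a writable file object; paths ending ``.gz`` are compressed."""
    if _is_path(sink):
        name = os.fspath(sink)
        os.makedirs(os.path.dirname(name) or ".", exist_ok=True)
        opener = gzip.open if name.endswith(".gz") else open
        mode = "wb" if binary else "wt"
        kwargs = {} if binary else {"newline": "\n"}
        with opener(name, mode, **kwargs) as fh:
            yield fh
    else:
        yield sink


def fmt_float(v: float) -> str:
    """Stable float formatting: shortest form with <= 6 significant digits."""
    s = f"{v:.6g}"
    # normalise "-0" and exponent forms like "1e+06"
    if s == "-0":
        s = "0"
    return s


def split_tokens(line: str) -> list:
    return line.split()


@dataclass
class WriteReport:
    """What a writer produced: files, row counts, and lossy field drops."""

    files: dict = field(default_factory=dict)   # role -> path or "<stream>"
    rows: dict = field(default_factory=dict)    # role -> row count
    lossy: list = field(default_factory=list)   # human-readable drop notes

    def note_loss(self, msg: str) -> None:
        if msg not in self.lossy:
            self.lossy.append(msg)


def sink_name(sink) -> str:
    return os.fspath(sink) if _is_path(sink) else "<stream>"
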