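"""FASTQ streaming I/O: gzip-aware reading and buffered gzip writing."""

from __future__ import annotations

import gzip
import io
from pathlib import Path
from typing import Iterator, Union

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .errors import FormatError

PathLike = Union[str, Path]

#: Default write-buffer size before a compressed flush (8 MiB).
DEFAULT_BUFFER_SIZE = 8 * 1024 * 1024


def open_text(path: PathLike) -> io.TextIOBase:
    """Open plain or gzip-compressed text, sniffing the gzip magic bytes."""
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fastq(path: PathLike) -> Iterator[tuple[str, str, str]]:
    """Yield (header, sequence, quality) tuples; header keeps its '@'."""
    with open_text(path) as fh:
        try:
            for title, seq, qual in FastqGeneralIterator(fh):
                yield "@" + title, seq, qual
        except ValueError as exc:
            raise FormatError(f"{path}: malformed FASTQ: {exc}") from exc


class BufferedGzipWriter:
    """Gzip writer that batches records in memory and compresses in chunks.

    Output is byte-valid gzip regardless of flush points. ``mtime=0`` keeps
    files byte-identical across runs with identical content.
    """

    def __init__(self, path: PathLike, buffer_size: int = DEFAULT_BUFFER_SIZE,
                 compresslevel: int = 4):
        self.path = Path(path)
        self.buffer_size = buffer_size
        self._gz = gzip.GzipFile(
            filename=str(self.path), mode="wb",
            compresslevel=compresslevel, mtime=0,
        )
        self._chunks: list[bytes] = []
        self._pending = 0

    def write(self, text: str) -> None:
        data = text.encode("ascii")
        self._chunks.append(data)
        self._pending += len(data)
        if self._pending >= self.buffer_size:
            self.flush()

    def write_record(self, header: str, seq: str, qual: str) -> None:
        self.write(f"{header}\n{seq}\n+\n{qual}\n")

    def flush(self) -> None:
        if self._chunks:
            self._gz.write(b"".join(self._chunks))
            self._chunks = []
            self._pending = 0

    def close(self) -> None:
        self.flush()
        self._gz.close()

    def __enter__(self) -> "BufferedGzipWriter":
        return self

    def __exit__(self, *exc) -> None:
        self.close()
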