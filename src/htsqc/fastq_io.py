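"""Gzip-aware FASTQ/FASTA reading and writing, paired-stream lockstep
iteration, and record-aligned chunk splitting.

FASTQ dialect is strict four-line records: Illumina writers emit exactly
one sequence and one quality line per read, and wrapped (multi-line)
FASTQ is ambiguous because quality lines may begin with ``@``. Gzip is
recognised by the two-byte magic number ``1f 8b``, never by filename.
"""

from __future__ import annotations

import gzip
import io
import os
import zlib
from dataclasses import dataclass
from typing import IO, Iterable, Iterator

from .errors import FastqParseError, GzipCorruptError, PairSyncError

GZIP_MAGIC = b"\x1f\x8b"

_VALID_BASES = frozenset("ACGTN")
# translation table used to uppercase and validate in one pass
_UPPER = str.maketrans("acgtn", "ACGTN")


@dataclass(frozen=True)
class SequenceRecord:
    """One FASTQ read.

    ``read_id`` is the token after ``@`` up to the first whitespace;
    ``description`` is the remainder of the header line (possibly empty).
    ``sequence`` is uppercase over {A, C, G, T, N} and has the same length
    as ``quality``.
    """

    read_id: str
    sequence: str
    quality: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def header(self) -> str:
        if self.description:
            return f"{self.read_id} {self.description}"
        return self.read_id


def pair_key(read_id: str) -> str:
    """Strip a trailing ``/1`` or ``/2`` mate designator.

    Casava 1.8-style headers (``@id 1:N:0:...``) keep the mate number in
    the description, so both mates already share an identical read_id and
    nothing is stripped.
    """
    if read_id.endswith(("/1", "/2")):
        return read_id[:-2]
    return read_id


@dataclass(frozen=True)
class ReadPair:
    r1: SequenceRecord
    r2: SequenceRecord

    @property
    def key(self) -> str:
        return pair_key(self.r1.read_id)


@dataclass(frozen=True)
class ChunkDescriptor:
    """A byte range of a plain (decompressed) FASTQ file that starts and
    ends on four-line record boundaries."""

    source_path: str
    start_byte: int
    end_byte: int
    record_count: int


def _is_gzip(path: str) -> bool:
    with open(path, "rb") as fh:
        return fh.read(2) == GZIP_MAGIC


def open_stream_auto(path: str) -> IO[str]:
    """Open ``path`` as a line-oriented text stream, transparently
    decompressing gzip content detected by magic bytes (the filename
    extension is ignored)."""
    if not os.path.exists(path):
        raise FastqParseError(f"input file not found: {path}")
    if _is_gzip(path):
        try:  # probe one byte so corruption fails early with a clear error
            with gzip.open(path, "rb") as probe:
                probe.read(1)
        except (OSError, EOFError, zlib.error) as exc:
            raise GzipCorruptError(f"corrupt gzip stream: {path}: {exc}") from exc
        return gzip.open(path, "rt", encoding="ascii", newline="")
    return open(path, "rt", encoding="ascii", newline="")


def normalize_sequence(raw: str, read_id: str) -> str:
    seq = raw.translate(_UPPER)
    if not set(seq) <= _VALID_BASES:
        bad = sorted(set(seq) - _VALID_BASES)
        raise FastqParseError(
            f"read '{read_id}': invalid base(s) {bad!r}; expected A/C/G/T/N"
        )
    return seq


def read_fastq(stream: Iterable[str]) -> Iterator[SequenceRecord]:
    """Yield records from a strict 4-line FASTQ text stream."""
    it = iter(stream)
    index = 0
    line_no = 0
    while True:
        header = next(it, None)
        if header is None:
            return
        line_no += 1
        header = header.rstrip("\n").rstrip("\r")
        if header == "" and next(it, None) is None:
            return  # tolerate a single trailing blank line at EOF
        if not header.startswith("@"):
            raise FastqParseError(
                f"line {line_no}: expected header starting '@', got {header[:30]!r}"
            )
        rest = [next(it, None) for _ in range(3)]
        if any(l is None for l in rest):
            raise FastqParseError(f"truncated record at record index {index}")
        line_no += 3
        seq_line, plus_line, qual_line = (l.rstrip("\n").rstrip("\r") for l in rest)  # type: ignore[union-attr]
        if not plus_line.startswith("+"):
            raise FastqParseError(
                f"record index {index}: separator line must start '+', got {plus_line[:30]!r}"
            )
        head = header[1:]
        read_id, _, description = head.partition(" ")
        sequence = normalize_sequence(seq_line, read_id)
        if len(sequence) != len(qual_line):
            raise FastqParseError(
                f"read '{read_id}': sequence length {len(sequence)} != "
                f"quality length {len(qual_line)}"
            )
        if qual_line and (min(qual_line) < "!" or max(qual_line) > "~"):
            raise FastqParseError(
                f"read '{read_id}': quality contains non-printable characters"
            )
        yield SequenceRecord(read_id, sequence, qual_line, description)
        index += 1


def read_fastq_path(path: str) -> Iterator[SequenceRecord]:
    with open_stream_auto(path) as stream:
        yield from read_fastq(stream)


def format_fastq(record: SequenceRecord) -> str:
    return f"@{record.header}\n{record.sequence}\n+\n{record.quality}\n"


def format_fasta(record: SequenceRecord) -> str:
    return f">{record.header}\n{record.sequence}\n"


def _open_out(path: str, gzip_out: bool) -> IO[str]:
    if gzip_out:
        # fixed mtime=0 keeps gzip output byte-deterministic across runs
        raw = open(path, "wb")
        gz = gzip.GzipFile(fileobj=raw, mode="wb", mtime=0)
        return io.TextIOWrapper(gz, encoding="ascii", newline="")
    return open(path, "wt", encoding="ascii", newline="")


def write_fastq(records: Iterable[SequenceRecord], path: str, gzip_out: bool = False) -> int:
    """Write records as 4-line FASTQ blocks; returns the number written."""
    n = 0
    with _open_out(path, gzip_out) as out:
        for rec in records:
            out.write(format_fastq(rec))
            n += 1
    return n


def write_fasta(records: Iterable[SequenceRecord], path: str) -> int:
    """Write records as two-line FASTA entries (quality discarded)."""
    n = 0
    with open(path, "wt", encoding="ascii", newline="") as out:
        for rec in records:
            out.write(format_fasta(rec))
            n += 1
    return n


def read_paired(stream1: Iterable[str], stream2: Iterable[str]) -> Iterator[ReadPair]:
    """Yield mate pairs in lockstep; any desynchronization is fatal."""
    it1 = read_fastq(stream1)
    it2 = read_fastq(stream2)
    index = 0
    while True:
        r1 = next(it1, None)
        r2 = next(it2, None)
        if r1 is None and r2 is None:
            return
        if r1 is None or r2 is None:
            short = "first" if r1 is None else "second"
            raise PairSyncError(
                f"pair desynchronization: {short} file ended at record index {index}"
            )
        if pair_key(r1.read_id) != pair_key(r2.read_id):
            raise PairSyncError(
                f"pair-key mismatch at record index {index}: "
                f"'{r1.read_id}' vs '{r2.read_id}'"
            )
        yield ReadPair(r1, r2)
        index += 1


def read_paired_paths(path1: str, path2: str) -> Iterator[ReadPair]:
    with open_stream_auto(path1) as s1, open_stream_auto(path2) as s2:
        yield from read_paired(s1, s2)


def decompress_to_plain(path: str, dest: str) -> str:
    """Decompress a gzip FASTQ to ``dest`` so byte offsets are meaningful;
    returns ``path`` unchanged if it is already plain text."""
    if not _is_gzip(path):
        return path
    with gzip.open(path, "rb") as src, open(dest, "wb") as out:
        while True:
            block = src.read(1 << 20)
            if not block:
                break
            out.write(block)
    return dest


def _looks_like_record_start(lines: list[str]) -> bool:
    """Guard for chunk-boundary search: a candidate header line must be
    followed by three lines that parse as the rest of a record. Quality
    lines that begin '@' fail this test because the line two below them
    is a sequence line, not a '+' separator."""
    if len(lines) < 4 or not lines[0].startswith("@"):
        return False
    seq = lines[1].rstrip("\n").rstrip("\r")
    plus = lines[2].rstrip("\n").rstrip("\r")
    qual = lines[3].rstrip("\n").rstrip("\r")
    if not plus.startswith("+"):
        return False
    if len(seq) != len(qual) or not seq:
        return False
    return set(seq.translate(_UPPER)) <= _VALID_BASES


def _next_record_start(fh: IO[bytes], approx: int, file_size: int) -> int:
    """Scan forward from ``approx`` to the next byte offset that starts a
    record, or ``file_size`` if none remains."""
    fh.seek(approx)
    if approx > 0:
        fh.readline()  # discard the partial line we landed in
    while True:
        pos = fh.tell()
        if pos >= file_size:
            return file_size
        window = [fh.readline().decode("ascii", "replace")]
        if not window[0]:
            return file_size
        probe = fh.tell()
        for _ in range(3):
            window.append(fh.readline().decode("ascii", "replace"))
        if _looks_like_record_start(window):
            fh.seek(pos)
            return pos
        fh.seek(probe)  # resume just after the rejected candidate line


def _count_records(path: str, start: int, end: int) -> int:
    n_lines = 0
    with open(path, "rb") as fh:
        fh.seek(start)
        remaining = end - start
        while remaining > 0:
            block = fh.read(min(1 << 20, remaining))
            if not block:
                break
            n_lines += block.count(b"\n")
            remaining -= len(block)
    if n_lines % 4 != 0:
        raise FastqParseError(
            f"{path}: byte range {start}-{end} holds {n_lines} lines, not a multiple of 4"
        )
    return n_lines // 4


def split_chunks(path: str, n_chunks: int) -> list[ChunkDescriptor]:
    """Partition a plain-text FASTQ into at most ``n_chunks`` contiguous,
    record-aligned byte ranges covering the file exactly once.

    Gzip inputs must be decompressed first (``decompress_to_plain``);
    gzip streams are not byte-seekable at record granularity.
    """
    if n_chunks < 1:
        raise ValueError(f"n_chunks must be >= 1, got {n_chunks}")
    if _is_gzip(path):
        raise ValueError("split_chunks requires a plain (decompressed) file")
    file_size = os.path.getsize(path)
    if file_size == 0:
        return []
    boundaries = [0]
    with open(path, "rb") as fh:
        for i in range(1, n_chunks):
            approx = file_size * i // n_chunks
            start = _next_record_start(fh, approx, file_size)
            if start > boundaries[-1] and start < file_size:
                boundaries.append(start)
    boundaries.append(file_size)
    chunks = []
    for start, end in zip(boundaries[:-1], boundaries[1:]):
        chunks.append(
            ChunkDescriptor(path, start, end, _count_records(path, start, end))
        )
    return chunks


def split_chunks_by_counts(path: str, record_counts: list[int]) -> list[ChunkDescriptor]:
    """Partition a plain FASTQ into chunks of exactly the given record
    counts (used to split a mate file at the same record indices as its
    partner)."""
    if _is_gzip(path):
        raise ValueError("split_chunks_by_counts requires a plain file")
    chunks: list[ChunkDescriptor] = []
    with open(path, "rb") as fh:
        pos = 0
        for count in record_counts:
            start = pos
            for _ in range(count * 4):
                if not fh.readline():
                    raise PairSyncError(
                        f"{path}: fewer records than its mate file"
                    )
            pos = fh.tell()
            chunks.append(ChunkDescriptor(path, start, pos, count))
        if fh.readline():
            raise PairSyncError(f"{path}: more records than its mate file")
    return chunks


def read_chunk(chunk: ChunkDescriptor) -> Iterator[SequenceRecord]:
    """Parse the records of one chunk by reading its byte range."""
    with open(chunk.source_path, "rb") as fh:
        fh.seek(chunk.start_byte)
        data = fh.read(chunk.end_byte - chunk.start_byte)
    text = data.decode("ascii")
    yield from read_fastq(io.StringIO(text))
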