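"""Serial and chunk-parallel execution of the trim/filter/stats pipeline.

The parallel path mirrors MapReduce: the input is split into
record-aligned chunks (paired files at identical record indices), each
chunk is processed by a worker process with the one encoding detected
up front, chunk outputs are concatenated in chunk order, and chunk
statistics are merged exactly. The combined output is byte-identical to
a serial run, and all intermediate part files and decompressed
temporaries are deleted automatically — on failure as well as success.

Rejected reads, when saved, are written in their original (untrimmed)
form so the reject file is always valid FASTQ.
"""

from __future__ import annotations

import itertools
import os
import shutil
import tempfile
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass
from typing import IO, Optional, Union

from . import fastq_io
from .errors import ConfigError, EncodingDetectionError
from .fastq_io import (
    ChunkDescriptor,
    ReadPair,
    SequenceRecord,
    decompress_to_plain,
    format_fasta,
    format_fastq,
    open_stream_auto,
    read_chunk,
    read_fastq,
    read_paired,
    split_chunks,
    split_chunks_by_counts,
)
from .pair_policy import resolve_pair
from .qc_stats import (
    QCStats,
    SampleResult,
    Tallies,
    merge_stats,
    merge_tallies,
    render_plots,
    render_summary,
)
from .quality_encoding import (
    ENCODINGS,
    QualityEncoding,
    decode_quality,
    detect_encoding,
)
from .read_filters import FilterConfig, evaluate_read


@dataclass
class RunOptions:
    """Output-shaping options common to serial and parallel runs."""

    gzip_out: bool = False
    fasta_out: bool = False
    keep_orphans: bool = False
    save_rejects: bool = False
    make_plots: bool = True

    def __post_init__(self) -> None:
        if self.gzip_out and self.fasta_out:
            raise ConfigError("gzip_out and fasta_out are mutually exclusive")


def sample_stem(path: str) -> str:
    name = os.path.basename(path)
    for ext in (".gz", ".fastq", ".fq"):
        if name.endswith(ext):
            name = name[: -len(ext)]
    return name


def _resolve_encoding(
    encoding: Union[str, QualityEncoding], paths: list[str]
) -> QualityEncoding:
    if isinstance(encoding, QualityEncoding):
        return encoding
    if encoding != "auto":
        try:
            return ENCODINGS[encoding]
        except KeyError:
            raise ConfigError(
                f"unknown quality format {encoding!r}; choose from "
                f"{sorted(ENCODINGS)} or 'auto'"
            ) from None

    def sample_records():
        for path in paths:
            with open_stream_auto(path) as fh:
                yield from read_fastq(fh)

    try:
        return detect_encoding(sample_records())
    except EncodingDetectionError:
        if any(next(read_fastq(open_stream_auto(p)), None) is not None for p in paths):
            raise
        # an empty input has nothing to decode; any encoding is vacuously fine
        return ENCODINGS["sanger_illumina18"]


class _Processor:
    """Per-read pipeline shared by the serial path and chunk workers so
    both produce identical records and identical statistics."""

    def __init__(self, config: FilterConfig, encoding: QualityEncoding,
                 keep_orphans: bool) -> None:
        self.config = config
        self.encoding = encoding
        self.keep_orphans = keep_orphans
        self.stats_raw = QCStats()
        self.stats_clean = QCStats()
        self.tallies = Tallies()

    def _observe_raw(self, record: SequenceRecord) -> None:
        self.stats_raw.update_read(
            record, decode_quality(record.quality, self.encoding, record.read_id)
        )

    def _observe_clean(self, record: SequenceRecord) -> None:
        self.stats_clean.update_read(
            record, decode_quality(record.quality, self.encoding, record.read_id)
        )

    def process_single(self, record, writers: "_Writers") -> None:
        self._observe_raw(record)
        verdict = evaluate_read(record, self.config, self.encoding)
        self.tallies.add_verdict(verdict, len(record))
        if verdict.passed:
            self._observe_clean(verdict.record)
            writers.write_clean1(verdict.record)
        elif writers.rejects is not None:
            writers.write_reject(record)

    def process_pair(self, pair: ReadPair, writers: "_Writers") -> None:
        self._observe_raw(pair.r1)
        self._observe_raw(pair.r2)
        v1 = evaluate_read(pair.r1, self.config, self.encoding)
        v2 = evaluate_read(pair.r2, self.config, self.encoding)
        self.tallies.add_verdict(v1, len(pair.r1))
        self.tallies.add_verdict(v2, len(pair.r2))
        outcome = resolve_pair(v1, v2, self.keep_orphans)
        self.tallies.add_routing(outcome.routing)
        if outcome.routing == "both_pass":
            self._observe_clean(v1.record)
            self._observe_clean(v2.record)
            writers.write_clean1(v1.record)
            writers.write_clean2(v2.record)
        elif outcome.routing == "orphan_r1":
            self._observe_clean(v1.record)
            writers.write_orphan1(v1.record)
            if writers.rejects is not None:
                writers.write_reject(pair.r2)
        elif outcome.routing == "orphan_r2":
            self._observe_clean(v2.record)
            writers.write_orphan2(v2.record)
            if writers.rejects is not None:
                writers.write_reject(pair.r1)
        elif writers.rejects is not None:
            writers.write_reject(pair.r1)
            writers.write_reject(pair.r2)


class _Writers:
    """Open text sinks for the cleaned/orphan/reject streams."""

    def __init__(self, clean1: IO[str], clean2: Optional[IO[str]] = None,
                 orphan1: Optional[IO[str]] = None, orphan2: Optional[IO[str]] = None,
                 rejects: Optional[IO[str]] = None, fasta_out: bool = False) -> None:
        self.clean1, self.clean2 = clean1, clean2
        self.orphan1, self.orphan2 = orphan1, orphan2
        self.rejects = rejects
        self._fmt = format_fasta if fasta_out else format_fastq

    def write_clean1(self, rec) -> None:
        self.clean1.write(self._fmt(rec))

    def write_clean2(self, rec) -> None:
        self.clean2.write(self._fmt(rec))

    def write_orphan1(self, rec) -> None:
        if self.orphan1 is not None:
            self.orphan1.write(self._fmt(rec))

    def write_orphan2(self, rec) -> None:
        if self.orphan2 is not None:
            self.orphan2.write(self._fmt(rec))

    def write_reject(self, rec) -> None:
        self.rejects.write(format_fastq(rec))

    def close(self) -> None:
        for fh in (self.clean1, self.clean2, self.orphan1, self.orphan2, self.rejects):
            if fh is not None:
                fh.close()


def _output_paths(r1: str, r2: Optional[str], out_dir: str, opts: RunOptions) -> dict:
    ext = ".fasta" if opts.fasta_out else (".fastq.gz" if opts.gzip_out else ".fastq")
    paths = {"clean1": os.path.join(out_dir, f"{sample_stem(r1)}_clean{ext}")}
    if r2 is not None:
        paths["clean2"] = os.path.join(out_dir, f"{sample_stem(r2)}_clean{ext}")
        if opts.keep_orphans:
            paths["unpaired1"] = os.path.join(out_dir, f"{sample_stem(r1)}_unpaired{ext}")
            paths["unpaired2"] = os.path.join(out_dir, f"{sample_stem(r2)}_unpaired{ext}")
    if opts.save_rejects:
        paths["rejects"] = os.path.join(out_dir, f"{sample_stem(r1)}_rejects.fastq")
    return paths


def _open_writers(paths: dict, opts: RunOptions) -> _Writers:
    gz = opts.gzip_out

    def opn(key, gzip_flag):
        if key not in paths:
            return None
        return fastq_io._open_out(paths[key], gzip_flag)

    return _Writers(
        clean1=fastq_io._open_out(paths["clean1"], gz),
        clean2=opn("clean2", gz),
        orphan1=opn("unpaired1", gz),
        orphan2=opn("unpaired2", gz),
        rejects=opn("rejects", False),
        fasta_out=opts.fasta_out,
    )


def _finalize(proc: _Processor, name: str, paths: dict, encoding: QualityEncoding,
              paired: bool, out_dir: str, opts: RunOptions) -> SampleResult:
    result = SampleResult(
        name=name,
        output_paths=dict(paths),
        stats_raw=proc.stats_raw,
        stats_clean=proc.stats_clean,
        encoding=encoding,
        tallies=proc.tallies,
        paired=paired,
    )
    result.output_paths["summary"] = render_summary(result, out_dir)
    if opts.make_plots:
        result.output_paths.update(render_plots(result, out_dir))
    return result


def run_serial(
    r1: str,
    r2: Optional[str] = None,
    config: Optional[FilterConfig] = None,
    encoding: Union[str, QualityEncoding] = "auto",
    out_dir: Optional[str] = None,
    sample_name: Optional[str] = None,
    options: Optional[RunOptions] = None,
) -> SampleResult:
    """Single-pass quality control of one sample.

    Detects the quality encoding on a bounded sample prefix, then streams
    every read (or mate pair) through trim -> filter -> route while
    accumulating raw and clean statistics, and writes the cleaned
    output(s), summary table, backing tables and plots.
    """
    config = config or FilterConfig()
    opts = options or RunOptions()
    out_dir = out_dir or os.path.dirname(os.path.abspath(r1))
    os.makedirs(out_dir, exist_ok=True)
    name = sample_name or sample_stem(r1)
    paths = [r1] if r2 is None else [r1, r2]
    enc = _resolve_encoding(encoding, paths)

    proc = _Processor(config, enc, opts.keep_orphans)
    out_paths = _output_paths(r1, r2, out_dir, opts)
    writers = _open_writers(out_paths, opts)
    try:
        if r2 is None:
            with open_stream_auto(r1) as fh:
                for record in read_fastq(fh):
                    proc.process_single(record, writers)
        else:
            with open_stream_auto(r1) as f1, open_stream_auto(r2) as f2:
                for pair in read_paired(f1, f2):
                    proc.process_pair(pair, writers)
    finally:
        writers.close()
    return _finalize(proc, name, out_paths, enc, r2 is not None, out_dir, opts)


@dataclass
class ChunkResult:
    chunk_index: int
    part_paths: dict
    stats_raw: QCStats
    stats_clean: QCStats
    tallies: Tallies


def _process_chunk(args) -> ChunkResult:
    (index, chunk1, chunk2, config, enc, opts, workdir) = args
    proc = _Processor(config, enc, opts.keep_orphans)
    part_paths = {"clean1": os.path.join(workdir, f"part{index:05d}_clean1")}
    if chunk2 is not None:
        part_paths["clean2"] = os.path.join(workdir, f"part{index:05d}_clean2")
        if opts.keep_orphans:
            part_paths["unpaired1"] = os.path.join(workdir, f"part{index:05d}_unp1")
            part_paths["unpaired2"] = os.path.join(workdir, f"part{index:05d}_unp2")
    if opts.save_rejects:
        part_paths["rejects"] = os.path.join(workdir, f"part{index:05d}_rej")
    handles = {k: open(p, "wt", encoding="ascii", newline="") for k, p in part_paths.items()}
    writers = _Writers(
        clean1=handles["clean1"],
        clean2=handles.get("clean2"),
        orphan1=handles.get("unpaired1"),
        orphan2=handles.get("unpaired2"),
        rejects=handles.get("rejects"),
        fasta_out=opts.fasta_out,
    )
    try:
        if chunk2 is None:
            for record in read_chunk(chunk1):
                proc.process_single(record, writers)
        else:
            records1 = read_chunk(chunk1)
            records2 = read_chunk(chunk2)
            index_base = 0
            for r1_rec, r2_rec in itertools.zip_longest(records1, records2):
                if r1_rec is None or r2_rec is None:
                    raise fastq_io.PairSyncError(
                        f"chunk {index}: mate chunks hold unequal record counts"
                    )
                if fastq_io.pair_key(r1_rec.read_id) != fastq_io.pair_key(r2_rec.read_id):
                    raise fastq_io.PairSyncError(
                        f"chunk {index} record {index_base}: pair-key mismatch "
                        f"'{r1_rec.read_id}' vs '{r2_rec.read_id}'"
                    )
                proc.process_pair(ReadPair(r1_rec, r2_rec), writers)
                index_base += 1
    finally:
        writers.close()
    return ChunkResult(index, part_paths, proc.stats_raw, proc.stats_clean, proc.tallies)


def _concat_parts(part_paths: list[str], dest: str, gzip_out: bool) -> None:
    with fastq_io._open_out(dest, gzip_out) as out:
        for part in part_paths:
            with open(part, "rt", encoding="ascii", newline="") as fh:
                shutil.copyfileobj(fh, out)


def cleanup_intermediates(workdir: str) -> None:
    """Best-effort, idempotent removal of the per-run working directory
    (chunk part files and decompressed temporaries)."""
    shutil.rmtree(workdir, ignore_errors=True)


def run_parallel(
    r1: str,
    r2: Optional[str] = None,
    config: Optional[FilterConfig] = None,
    encoding: Union[str, QualityEncoding] = "auto",
    out_dir: Optional[str] = None,
    sample_name: Optional[str] = None,
    options: Optional[RunOptions] = None,
    n_cpus: int = 2,
) -> SampleResult:
    """Chunk-parallel quality control whose outputs are byte-identical to
    :func:`run_serial` on the same input and configuration.

    The default of two worker processes matches the tool's conservative
    out-of-the-box footprint; raise ``n_cpus`` to use more cores.
    """
    if n_cpus < 1:
        raise ConfigError("n_cpus must be >= 1")
    config = config or FilterConfig()
    opts = options or RunOptions()
    out_dir = out_dir or os.path.dirname(os.path.abspath(r1))
    os.makedirs(out_dir, exist_ok=True)
    name = sample_name or sample_stem(r1)
    enc = _resolve_encoding(encoding, [r1] if r2 is None else [r1, r2])

    workdir = tempfile.mkdtemp(prefix=f"htsqc_{name}_", dir=out_dir)
    try:
        plain1 = decompress_to_plain(r1, os.path.join(workdir, "in1.fastq"))
        chunks1 = split_chunks(plain1, n_cpus)
        chunks2: list[Optional[ChunkDescriptor]]
        if r2 is not None:
            plain2 = decompress_to_plain(r2, os.path.join(workdir, "in2.fastq"))
            chunks2 = list(
                split_chunks_by_counts(plain2, [c.record_count for c in chunks1])
            )
        else:
            chunks2 = [None] * len(chunks1)

        jobs = [
            (i, c1, c2, config, enc, opts, workdir)
            for i, (c1, c2) in enumerate(zip(chunks1, chunks2))
        ]
        if len(jobs) <= 1 or n_cpus == 1:
            results = [_process_chunk(job) for job in jobs]
        else:
            with ProcessPoolExecutor(max_workers=min(n_cpus, len(jobs))) as pool:
                results = list(pool.map(_process_chunk, jobs))
        results.sort(key=lambda r: r.chunk_index)

        out_paths = _output_paths(r1, r2, out_dir, opts)
        for key, dest in out_paths.items():
            parts = [r.part_paths[key] for r in results if key in r.part_paths]
            gz = opts.gzip_out and key != "rejects"
            _concat_parts(parts, dest, gz)

        proc = _Processor(config, enc, opts.keep_orphans)
        for r in results:
            proc.stats_raw = merge_stats(proc.stats_raw, r.stats_raw)
            proc.stats_clean = merge_stats(proc.stats_clean, r.stats_clean)
            proc.tallies = merge_tallies(proc.tallies, r.tallies)
        return _finalize(proc, name, out_paths, enc, r2 is not None, out_dir, opts)
    except Exception:
        # remove any partially written final outputs before propagating
        for dest in _output_paths(r1, r2, out_dir, opts).values():
            if os.path.exists(dest):
                try:
                    os.remove(dest)
                except OSError:
                    pass
        raise
    finally:
        cleanup_intermediates(workdir)
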