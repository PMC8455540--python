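"""Streaming, mergeable QC statistics and report rendering.

A :class:`QCStats` accumulator is updated one read at a time and two
accumulators can be merged exactly (all fields are sums, counts or
min/max), so chunk-parallel processing reproduces the single-pass
statistics. Reports overlay raw vs. cleaned data: mean Phred per
position, the per-read mean-quality distribution, the per-read GC
distribution, and per-position base composition. Every plot's numeric
content is also written as a tab-separated backing table.

Conventions: the per-read GC bin is round-half-up of the GC percentage
(N bases excluded from numerator and denominator; reads with zero
called bases are excluded from the histogram and tallied separately);
the per-read quality bin is the floor of the mean Phred score, clamped
to [0, 60]. The "average Phred quality" of a dataset is the unweighted
mean over reads of the per-read mean score — the same statistic the
quality filter thresholds.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .fastq_io import SequenceRecord
from .quality_encoding import QualityEncoding

_BASES = "ACGTN"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
GC_BINS = 101
QUAL_BINS = 61  # floor of mean Phred, clamped to 0..60


def gc_percent(sequence: str) -> Optional[float]:
    """GC percentage over called bases, or None if no base was called."""
    called = len(sequence) - sequence.count("N")
    if called == 0:
        return None
    gc = sequence.count("G") + sequence.count("C")
    return 100.0 * gc / called


class QCStats:
    """Mergeable accumulator of read-level and position-level QC counters."""

    __slots__ = (
        "n_reads", "n_bases", "min_len", "max_len", "sum_len",
        "sum_mean_quality", "n_no_called_bases",
        "pos_quality_sum", "pos_count", "base_counts",
        "gc_histogram", "read_quality_histogram",
    )

    def __init__(self) -> None:
        self.n_reads = 0
        self.n_bases = 0
        self.min_len: Optional[int] = None
        self.max_len: Optional[int] = None
        self.sum_len = 0
        self.sum_mean_quality = 0.0
        self.n_no_called_bases = 0
        self.pos_quality_sum = np.zeros(0, dtype=np.float64)
        self.pos_count = np.zeros(0, dtype=np.int64)
        self.base_counts = np.zeros((5, 0), dtype=np.int64)
        self.gc_histogram = np.zeros(GC_BINS, dtype=np.int64)
        self.read_quality_histogram = np.zeros(QUAL_BINS, dtype=np.int64)

    def _grow(self, length: int) -> None:
        cur = self.pos_count.shape[0]
        if length <= cur:
            return
        self.pos_quality_sum = np.concatenate(
            [self.pos_quality_sum, np.zeros(length - cur)]
        )
        self.pos_count = np.concatenate(
            [self.pos_count, np.zeros(length - cur, dtype=np.int64)]
        )
        self.base_counts = np.concatenate(
            [self.base_counts, np.zeros((5, length - cur), dtype=np.int64)], axis=1
        )

    def update_read(self, record: SequenceRecord, phreds: Sequence[float]) -> None:
        """Fold one read (with its decoded Phred scores) into the counters."""
        length = len(record)
        if length == 0:
            return
        self.n_reads += 1
        self.n_bases += length
        self.sum_len += length
        self.min_len = length if self.min_len is None else min(self.min_len, length)
        self.max_len = length if self.max_len is None else max(self.max_len, length)

        mean_q = sum(phreds) / length
        self.sum_mean_quality += mean_q
        qbin = min(max(int(math.floor(mean_q)), 0), QUAL_BINS - 1)
        self.read_quality_histogram[qbin] += 1

        gc = gc_percent(record.sequence)
        if gc is None:
            self.n_no_called_bases += 1
        else:
            self.gc_histogram[int(math.floor(gc + 0.5))] += 1  # round half up

        self._grow(length)
        self.pos_count[:length] += 1
        self.pos_quality_sum[:length] += np.asarray(phreds, dtype=np.float64)
        seq = np.frombuffer(record.sequence.encode("ascii"), dtype=np.uint8)
        for i, base in enumerate(_BASES):
            self.base_counts[i, :length] += seq == ord(base)

    # -- derived aggregates -------------------------------------------------

    @property
    def mean_length(self) -> Optional[float]:
        return self.sum_len / self.n_reads if self.n_reads else None

    @property
    def mean_read_quality(self) -> Optional[float]:
        return self.sum_mean_quality / self.n_reads if self.n_reads else None

    def per_position_mean_quality(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(
                self.pos_count > 0, self.pos_quality_sum / self.pos_count, np.nan
            )


def merge_stats(a: QCStats, b: QCStats) -> QCStats:
    """Exact merge: equivalent to accumulating the concatenated stream."""
    out = QCStats()
    out.n_reads = a.n_reads + b.n_reads
    out.n_bases = a.n_bases + b.n_bases
    mins = [m for m in (a.min_len, b.min_len) if m is not None]
    maxs = [m for m in (a.max_len, b.max_len) if m is not None]
    out.min_len = min(mins) if mins else None
    out.max_len = max(maxs) if maxs else None
    out.sum_len = a.sum_len + b.sum_len
    out.sum_mean_quality = a.sum_mean_quality + b.sum_mean_quality
    out.n_no_called_bases = a.n_no_called_bases + b.n_no_called_bases
    length = max(a.pos_count.shape[0], b.pos_count.shape[0])
    out._grow(length)
    for src in (a, b):
        n = src.pos_count.shape[0]
        out.pos_quality_sum[:n] += src.pos_quality_sum
        out.pos_count[:n] += src.pos_count
        out.base_counts[:, :n] += src.base_counts
    out.gc_histogram = a.gc_histogram + b.gc_histogram
    out.read_quality_histogram = a.read_quality_histogram + b.read_quality_histogram
    return out


@dataclass
class Tallies:
    """Per-read verdict accounting for one sample (or one chunk).

    ``n_trimmed`` counts *retained* reads that were shortened — the
    paper-style distinction between trimmed (shortened, kept) and
    filtered (discarded). ``rejected_bases`` counts the original,
    pre-trim bases of discarded reads so that base conservation holds:
    raw bases == clean bases + rejected bases + bases trimmed from
    passing reads.
    """

    n_pass: int = 0
    too_short: int = 0
    too_many_n: int = 0
    low_mean_quality: int = 0
    n_trimmed: int = 0
    adapter_bases_removed: int = 0
    quality_bases_removed: int = 0
    rejected_bases: int = 0
    both_pass: int = 0
    both_drop: int = 0
    orphan_r1: int = 0
    orphan_r2: int = 0

    @property
    def n_fail(self) -> int:
        return self.too_short + self.too_many_n + self.low_mean_quality

    @property
    def n_reads(self) -> int:
        return self.n_pass + self.n_fail

    def add_verdict(self, verdict, original_len: int) -> None:
        if verdict.passed:
            self.n_pass += 1
            if verdict.trim.was_trimmed:
                self.n_trimmed += 1
            self.adapter_bases_removed += verdict.trim.adapter_bases_removed
            self.quality_bases_removed += verdict.trim.quality_bases_removed
        else:
            setattr(self, verdict.fail_reason, getattr(self, verdict.fail_reason) + 1)
            self.rejected_bases += original_len

    def add_routing(self, routing: str) -> None:
        setattr(self, routing, getattr(self, routing) + 1)


def merge_tallies(a: Tallies, b: Tallies) -> Tallies:
    out = Tallies()
    for f in Tallies.__dataclass_fields__:
        setattr(out, f, getattr(a, f) + getattr(b, f))
    return out


@dataclass
class SampleResult:
    """Everything produced for one sample: output paths, raw and clean
    statistics, the detected encoding, and verdict tallies."""

    name: str
    output_paths: dict
    stats_raw: QCStats
    stats_clean: QCStats
    encoding: QualityEncoding
    tallies: Tallies
    paired: bool = False


# ---------------------------------------------------------------------------
# report rendering


def _fmt(value, nd: int = 4) -> str:
    if value is None:
        return "NA"
    if isinstance(value, float):
        return f"{value:.{nd}f}"
    return str(value)


def render_summary(result: SampleResult, outdir: str) -> str:
    """Write the per-sample summary table; returns its path."""
    raw, clean, t = result.stats_raw, result.stats_clean, result.tallies
    rows = [
        ("sample", result.name),
        ("sequence_quality_format", result.encoding.name),
        ("read_type", "paired" if result.paired else "single"),
        ("raw_reads", raw.n_reads),
        ("clean_reads", clean.n_reads),
        ("raw_bases", raw.n_bases),
        ("clean_bases", clean.n_bases),
        ("raw_min_length", _fmt(raw.min_len)),
        ("raw_max_length", _fmt(raw.max_len)),
        ("raw_mean_length", _fmt(raw.mean_length)),
        ("clean_min_length", _fmt(clean.min_len)),
        ("clean_max_length", _fmt(clean.max_len)),
        ("clean_mean_length", _fmt(clean.mean_length)),
        ("raw_mean_read_quality", _fmt(raw.mean_read_quality)),
        ("clean_mean_read_quality", _fmt(clean.mean_read_quality)),
        ("reads_passed", t.n_pass),
        ("reads_failed_too_short", t.too_short),
        ("reads_failed_too_many_n", t.too_many_n),
        ("reads_failed_low_mean_quality", t.low_mean_quality),
        ("reads_trimmed", t.n_trimmed),
        ("adapter_bases_removed", t.adapter_bases_removed),
        ("quality_bases_removed", t.quality_bases_removed),
    ]
    if result.paired:
        rows += [
            ("pairs_both_pass", t.both_pass),
            ("pairs_both_drop", t.both_drop),
            ("orphans_r1", t.orphan_r1),
            ("orphans_r2", t.orphan_r2),
        ]
    path = os.path.join(outdir, f"{result.name}_summary.tsv")
    with open(path, "w", encoding="ascii", newline="") as fh:
        fh.write("field\tvalue\n")
        for key, value in rows:
            fh.write(f"{key}\t{value}\n")
    return path


def _pct(counts: np.ndarray) -> np.ndarray:
    total = counts.sum()
    if total == 0:
        return np.zeros_like(counts, dtype=np.float64)
    return 100.0 * counts / total


def render_tables(result: SampleResult, outdir: str) -> dict:
    """Write the four backing tables; returns {table name: path}."""
    raw, clean = result.stats_raw, result.stats_clean
    name = result.name
    paths = {}

    length = max(raw.pos_count.shape[0], clean.pos_count.shape[0])

    def padded(arr: np.ndarray, fill=np.nan) -> np.ndarray:
        out = np.full(length, fill, dtype=np.float64)
        out[: arr.shape[0]] = arr
        return out

    pq = pd.DataFrame(
        {
            "position": np.arange(1, length + 1),
            "raw_mean_quality": padded(raw.per_position_mean_quality()),
            "clean_mean_quality": padded(clean.per_position_mean_quality()),
        }
    )
    paths["per_position_quality"] = os.path.join(
        outdir, f"{name}_per_position_quality.tsv"
    )
    pq.to_csv(paths["per_position_quality"], sep="\t", index=False,
              float_format="%.6f", na_rep="NA")

    qh = pd.DataFrame(
        {
            "mean_quality_bin": np.arange(QUAL_BINS),
            "raw_percent": _pct(raw.read_quality_histogram),
            "clean_percent": _pct(clean.read_quality_histogram),
        }
    )
    paths["read_quality_hist"] = os.path.join(outdir, f"{name}_read_quality_hist.tsv")
    qh.to_csv(paths["read_quality_hist"], sep="\t", index=False, float_format="%.6f")

    gh = pd.DataFrame(
        {
            "gc_percent_bin": np.arange(GC_BINS),
            "raw_percent": _pct(raw.gc_histogram),
            "clean_percent": _pct(clean.gc_histogram),
        }
    )
    paths["gc_hist"] = os.path.join(outdir, f"{name}_gc_hist.tsv")
    gh.to_csv(paths["gc_hist"], sep="\t", index=False, float_format="%.6f")

    def base_pct(stats: QCStats) -> np.ndarray:
        counts = np.full((5, length), 0.0)
        n = stats.base_counts.shape[1]
        counts[:, :n] = stats.base_counts
        totals = counts.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(totals > 0, 100.0 * counts / totals, np.nan)

    raw_pct = base_pct(raw)
    clean_pct = base_pct(clean)
    bc = pd.DataFrame({"position": np.arange(1, length + 1)})
    for i, base in enumerate(_BASES):
        bc[f"raw_pct_{base}"] = raw_pct[i]
    for i, base in enumerate(_BASES):
        bc[f"clean_pct_{base}"] = clean_pct[i]
    paths["base_composition"] = os.path.join(outdir, f"{name}_base_composition.tsv")
    bc.to_csv(paths["base_composition"], sep="\t", index=False,
              float_format="%.6f", na_rep="NA")
    return paths


def render_plots(result: SampleResult, outdir: str) -> dict:
    """Write the four QC figures (PNG) plus their backing tables.

    Returns {artifact name: path} for all eight files. Plots overlay the
    raw and cleaned datasets; the tables carry the exact numbers so
    downstream checks never depend on image bytes.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths = render_tables(result, outdir)
    raw, clean = result.stats_raw, result.stats_clean
    name = result.name
    length = max(raw.pos_count.shape[0], clean.pos_count.shape[0])
    positions = np.arange(1, length + 1)

    def padded(arr, fill=np.nan):
        out = np.full(length, fill, dtype=np.float64)
        out[: arr.shape[0]] = arr
        return out

    # (A) mean Phred per position
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(positions, padded(raw.per_position_mean_quality()), label="raw")
    ax.plot(positions, padded(clean.per_position_mean_quality()), label="clean")
    ax.set_xlabel("Position in read (bp)")
    ax.set_ylabel("Mean Phred quality")
    ax.set_title(f"{name}: per-position quality")
    ax.legend()
    paths["per_position_quality_png"] = os.path.join(
        outdir, f"{name}_per_position_quality.png"
    )
    fig.savefig(paths["per_position_quality_png"], dpi=110)
    plt.close(fig)

    # (B) per-read mean quality distribution
    fig, ax = plt.subplots(figsize=(7, 4))
    bins = np.arange(QUAL_BINS)
    ax.bar(bins - 0.2, _pct(raw.read_quality_histogram), width=0.4, label="raw")
    ax.bar(bins + 0.2, _pct(clean.read_quality_histogram), width=0.4, label="clean")
    ax.set_xlabel("Mean Phred quality of read")
    ax.set_ylabel("Percent of reads")
    ax.set_title(f"{name}: read quality distribution")
    ax.legend()
    paths["read_quality_hist_png"] = os.path.join(
        outdir, f"{name}_read_quality_hist.png"
    )
    fig.savefig(paths["read_quality_hist_png"], dpi=110)
    plt.close(fig)

    # (C) GC content distribution
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(np.arange(GC_BINS), _pct(raw.gc_histogram), label="raw")
    ax.plot(np.arange(GC_BINS), _pct(clean.gc_histogram), label="clean")
    ax.set_xlabel("GC content (%)")
    ax.set_ylabel("Percent of reads")
    ax.set_title(f"{name}: GC content distribution")
    ax.legend()
    paths["gc_hist_png"] = os.path.join(outdir, f"{name}_gc_hist.png")
    fig.savefig(paths["gc_hist_png"], dpi=110)
    plt.close(fig)

    # (D) per-position base composition
    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
    for ax, stats, label in ((axes[0], raw, "raw"), (axes[1], clean, "clean")):
        n = stats.base_counts.shape[1]
        totals = stats.base_counts.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = np.where(totals > 0, 100.0 * stats.base_counts / totals, np.nan)
        for i, base in enumerate(_BASES):
            ax.plot(np.arange(1, n + 1), pct[i], label=base)
        ax.set_xlabel("Position in read (bp)")
        ax.set_title(label)
    axes[0].set_ylabel("Percent of bases")
    axes[1].legend(ncol=5, fontsize=8)
    fig.suptitle(f"{name}: base composition")
    paths["base_composition_png"] = os.path.join(outdir, f"{name}_base_composition.png")
    fig.savefig(paths["base_composition_png"], dpi=110)
    plt.close(fig)
    return paths
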