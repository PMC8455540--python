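"""Per-read trimming + filtering pipeline with single-reason verdicts.

The order of operations is fixed: adapter trimming, then 3' quality
trimming, then filters on the post-trim read — length, uncalled-base
content, and mean Phred quality. The first failing filter sets the fail
reason and later checks are skipped, so per-reason tallies always sum to
the input read count.

By default only the mean-quality filter is active: reads whose average
per-base Phred score is strictly below 20 are discarded (mean exactly 20
passes; Q20 corresponds to 99% base-call accuracy).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .errors import ConfigError
from .fastq_io import SequenceRecord
from .quality_encoding import QualityEncoding, decode_quality, mean_quality
from .trimming import AdapterSet, TrimResult, trim_adapter, trim_quality_3prime

FAIL_REASONS = ("too_short", "too_many_n", "low_mean_quality")


@dataclass(frozen=True)
class FilterConfig:
    """Active thresholds; ``None`` disables an optional filter."""

    min_mean_quality: float = 20.0
    max_n: Optional[int] = None
    max_n_fraction: Optional[float] = None
    min_length: int = 0
    trim_quality_threshold: Optional[float] = None
    adapters: Optional[AdapterSet] = None

    def __post_init__(self) -> None:
        if self.max_n is not None and self.max_n_fraction is not None:
            raise ConfigError("max_n and max_n_fraction are mutually exclusive")
        if self.max_n is not None and self.max_n < 0:
            raise ConfigError("max_n must be >= 0")
        if self.max_n_fraction is not None and not 0.0 <= self.max_n_fraction <= 1.0:
            raise ConfigError("max_n_fraction must be in [0, 1]")
        if self.min_length < 0:
            raise ConfigError("min_length must be >= 0")


@dataclass(frozen=True)
class ReadVerdict:
    status: str  # "pass" | "fail"
    fail_reason: Optional[str]  # None | one of FAIL_REASONS
    trim: TrimResult

    @property
    def passed(self) -> bool:
        return self.status == "pass"

    @property
    def record(self) -> SequenceRecord:
        return self.trim.record


def count_uncalled(sequence: str) -> int:
    """Number of uncalled (N) bases in a normalized sequence."""
    return sequence.count("N")


def evaluate_read(
    record: SequenceRecord, config: FilterConfig, encoding: QualityEncoding
) -> ReadVerdict:
    """Trim and filter one read, returning a single-reason verdict."""
    original_len = len(record)
    adapter_removed = 0
    quality_removed = 0
    current = record
    if config.adapters is not None:
        t = trim_adapter(current, config.adapters)
        current = t.record
        adapter_removed = t.adapter_bases_removed
    if config.trim_quality_threshold is not None and len(current) > 0:
        t = trim_quality_3prime(current, config.trim_quality_threshold, encoding)
        current = t.record
        quality_removed = t.quality_bases_removed
    trim = TrimResult(current, adapter_removed, quality_removed)

    # zero-length reads always fail: empty sequences are invalid FASTQ output
    if len(current) < max(config.min_length, 1):
        return ReadVerdict("fail", "too_short", trim)

    n_count = count_uncalled(current.sequence)
    if config.max_n is not None and n_count > config.max_n:
        return ReadVerdict("fail", "too_many_n", trim)
    if (
        config.max_n_fraction is not None
        and n_count / len(current) > config.max_n_fraction
    ):
        return ReadVerdict("fail", "too_many_n", trim)

    scores = decode_quality(current.quality, encoding, current.read_id)
    if mean_quality(scores) < config.min_mean_quality:
        return ReadVerdict("fail", "low_mean_quality", trim)

    return ReadVerdict("pass", None, trim)
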