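"""Adapter/primer trimming and 3' low-quality trimming.

Adapter matching targets the dominant Illumina read-through scenario:
the library adapter appears at the 3' end of the read (possibly only a
prefix of it, when the read ends inside the adapter). Matching is a
Hamming-distance scan — leftmost match wins, ties broken by adapter
order — and the read is truncated at the match start, removing the
adapter and everything downstream of it. Only 3' trimming is performed.

Quality trimming removes the maximal 3' suffix in which every base is
below a fixed Phred threshold (FASTX-style), which is deterministic,
order-independent, and idempotent.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace
from typing import Optional

from .errors import ConfigError
from .fastq_io import SequenceRecord, open_stream_auto
from .quality_encoding import QualityEncoding, decode_quality

MIN_ADAPTER_OVERLAP = 5


@dataclass(frozen=True)
class AdapterSet:
    """Ordered adapters (user order breaks position ties) and an allowed
    mismatch fraction of the aligned length."""

    adapters: tuple[str, ...]
    max_mismatch_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not self.adapters:
            raise ConfigError("adapter set is empty")
        for a in self.adapters:
            if len(a) < MIN_ADAPTER_OVERLAP:
                raise ConfigError(f"adapter {a!r} shorter than {MIN_ADAPTER_OVERLAP} bases")
            if not set(a) <= set("ACGT"):
                raise ConfigError(f"adapter {a!r} contains characters outside A/C/G/T")
        if not 0.0 <= self.max_mismatch_fraction < 1.0:
            raise ConfigError("max_mismatch_fraction must be in [0, 1)")


def load_adapters(spec: str, max_mismatch_fraction: float = 0.0) -> AdapterSet:
    """Build an AdapterSet from a FASTA file path or a comma-separated
    list of sequences (FASTA headers are ignored)."""
    adapters: list[str] = []
    if os.path.exists(spec):
        with open_stream_auto(spec) as fh:
            current: list[str] = []
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith(">"):
                    if current:
                        adapters.append("".join(current).upper())
                        current = []
                else:
                    current.append(line)
            if current:
                adapters.append("".join(current).upper())
    else:
        adapters = [a.strip().upper() for a in spec.split(",") if a.strip()]
    return AdapterSet(tuple(adapters), max_mismatch_fraction)


@dataclass(frozen=True)
class TrimResult:
    """Outcome of trimming one read; output sequence is always a prefix
    of the input sequence."""

    record: SequenceRecord
    adapter_bases_removed: int = 0
    quality_bases_removed: int = 0

    @property
    def was_trimmed(self) -> bool:
        return (self.adapter_bases_removed + self.quality_bases_removed) > 0


def _hamming_at(sequence: str, adapter: str, p: int, max_mm: int) -> bool:
    mm = 0
    aligned = min(len(adapter), len(sequence) - p)
    for i in range(aligned):
        c = sequence[p + i]
        if c == "N" or c != adapter[i]:
            mm += 1
            if mm > max_mm:
                return False
    return True


def find_adapter(sequence: str, adapters: AdapterSet) -> Optional[tuple[int, int]]:
    """Locate the leftmost adapter occurrence.

    Returns ``(adapter_index, start_position)`` or ``None``. At each read
    position, adapters are tried in user order; a partial match hanging
    off the 3' end needs at least MIN_ADAPTER_OVERLAP aligned bases. An
    'N' in the read always counts as a mismatch.
    """
    n = len(sequence)
    mmf = adapters.max_mismatch_fraction
    for p in range(0, n - MIN_ADAPTER_OVERLAP + 1):
        for idx, adapter in enumerate(adapters.adapters):
            aligned = min(len(adapter), n - p)
            if aligned < MIN_ADAPTER_OVERLAP:
                continue
            max_mm = int(mmf * aligned)
            if _hamming_at(sequence, adapter, p, max_mm):
                return idx, p
    return None


def _truncate(record: SequenceRecord, length: int) -> SequenceRecord:
    return replace(
        record, sequence=record.sequence[:length], quality=record.quality[:length]
    )


def trim_adapter(record: SequenceRecord, adapters: AdapterSet) -> TrimResult:
    """Remove the adapter and all bases 3' of it (read-through model)."""
    hit = find_adapter(record.sequence, adapters)
    if hit is None:
        return TrimResult(record)
    _, p = hit
    removed = len(record) - p
    return TrimResult(_truncate(record, p), adapter_bases_removed=removed)


def trim_quality_3prime(
    record: SequenceRecord, per_base_threshold: float, encoding: QualityEncoding
) -> TrimResult:
    """Trim the maximal 3' suffix in which every base has Phred score
    below ``per_base_threshold``."""
    scores = decode_quality(record.quality, encoding, record.read_id)
    keep = len(scores)
    while keep > 0 and scores[keep - 1] < per_base_threshold:
        keep -= 1
    if keep == len(scores):
        return TrimResult(record)
    return TrimResult(_truncate(record, keep), quality_bases_removed=len(scores) - keep)
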