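"""Shared fixtures and an independent brute-force per-read oracle.

The oracle recomputes trim and filter outcomes directly from the raw
FASTQ strings with naive, unoptimized logic (all-positions substring
scans, character arithmetic) so pipeline tests never check the
implementation against itself.
"""

from __future__ import annotations

import math

import pytest


def write_lines(path, lines):
    with open(path, "wt", newline="") as fh:
        fh.write("".join(line + "\n" for line in lines))
    return str(path)


def fastq_lines(reads):
    """reads: list of (id, seq, qual) -> flat 4-line blocks."""
    lines = []
    for rid, seq, qual in reads:
        lines += [f"@{rid}", seq, "+", qual]
    return lines


def parse_fastq_naive(path):
    """Minimal independent FASTQ reader used only by oracles."""
    reads = []
    with open(path) as fh:
        lines = [l.rstrip("\n") for l in fh]
    lines = [l for l in lines if l != ""] if lines and lines[-1] == "" else lines
    assert len(lines) % 4 == 0
    for i in range(0, len(lines), 4):
        rid = lines[i][1:].split(" ")[0]
        reads.append((rid, lines[i + 1].upper(), lines[i + 3]))
    return reads


def oracle_phred(qual, offset=33, solexa=False):
    if solexa:
        return [10 * math.log10(10 ** ((ord(c) - 64) / 10) + 1) for c in qual]
    return [ord(c) - offset for c in qual]


def oracle_find_adapter(seq, adapters, mmf=0.0, min_overlap=5):
    """All-positions exhaustive scan; leftmost position, then adapter order."""
    best = None
    for idx, ad in enumerate(adapters):
        for p in range(len(seq)):
            aligned = min(len(ad), len(seq) - p)
            if aligned < min_overlap:
                break
            mm = sum(
                1
                for i in range(aligned)
                if seq[p + i] == "N" or seq[p + i] != ad[i]
            )
            if mm <= math.floor(mmf * aligned):
                if best is None or p < best[1] or (p == best[1] and idx < best[0]):
                    best = (idx, p)
                break
    return best


def oracle_evaluate(
    seq,
    qual,
    offset=33,
    min_mean_quality=20.0,
    adapters=None,
    adapter_mismatch=0.0,
    trim_quality_threshold=None,
    max_n=None,
    max_n_fraction=None,
    min_length=0,
):
    """Independent recomputation of one read's verdict from raw strings.

    Returns (status, fail_reason, kept_length, adapter_removed, quality_removed).
    """
    adapter_removed = quality_removed = 0
    if adapters:
        hit = oracle_find_adapter(seq, adapters, adapter_mismatch)
        if hit is not None:
            adapter_removed = len(seq) - hit[1]
            seq, qual = seq[: hit[1]], qual[: hit[1]]
    if trim_quality_threshold is not None:
        scores = oracle_phred(qual, offset)
        keep = len(scores)
        while keep > 0 and scores[keep - 1] < trim_quality_threshold:
            keep -= 1
        quality_removed = len(scores) - keep
        seq, qual = seq[:keep], qual[:keep]
    if len(seq) < max(min_length, 1):
        return ("fail", "too_short", len(seq), adapter_removed, quality_removed)
    n = seq.count("N")
    if max_n is not None and n > max_n:
        return ("fail", "too_many_n", len(seq), adapter_removed, quality_removed)
    if max_n_fraction is not None and n / len(seq) > max_n_fraction:
        return ("fail", "too_many_n", len(seq), adapter_removed, quality_removed)
    scores = oracle_phred(qual, offset)
    if sum(scores) / len(scores) < min_mean_quality:
        return ("fail", "low_mean_quality", len(seq), adapter_removed, quality_removed)
    return ("pass", None, len(seq), adapter_removed, quality_removed)


@pytest.fixture
def tmp_fastq(tmp_path):
    def _make(reads, name="reads.fastq"):
        return write_lines(tmp_path / name, fastq_lines(reads))

    return _make
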