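"""Seeded synthetic FASTQ generation with per-read ground truth.

The generator emulates the artifacts the pipeline targets: a two-band
per-read quality mixture (a ``f_low`` fraction of reads draw every base
quality uniformly from a low band, the rest from a high band), adapter
read-through contamination inserted at known positions, uncalled-base
(N) spikes, and paired files with lockstep ids. Every read's truth —
stratum, mean quality, adapter position, N count — is written to a
tab-separated sidecar so expected trim and filter outcomes are
computable without running the pipeline.

Identical spec + seed always produce byte-identical files. For
offset-33 specs with a low-quality fraction, the first read is pinned
to the low band so the file always contains a character below ASCII 59
and encoding detection is decidable.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd

from .errors import ConfigError
from .quality_encoding import ENCODINGS, QualityEncoding, solexa_to_phred

ILLUMINA_ADAPTER = "AGATCGGAAGAGC"


@dataclass(frozen=True)
class AdapterSpec:
    """Adapter contamination model: a ``fraction`` of reads carry the
    adapter starting at ``position`` (an int, or an inclusive (lo, hi)
    range sampled uniformly); bases from the position onward are
    overwritten by the adapter then by random fill."""

    sequence: str = ILLUMINA_ADAPTER
    position: Union[int, tuple[int, int]] = 20
    fraction: float = 0.5


@dataclass(frozen=True)
class FixtureSpec:
    n_reads: int = 1000
    read_length: Union[int, tuple[int, int]] = 100
    encoding: str = "sanger_illumina18"
    f_low: float = 0.0
    low_band: tuple[int, int] = (2, 15)
    high_band: tuple[int, int] = (25, 40)
    adapter: Optional[AdapterSpec] = None
    n_fraction: float = 0.0
    n_per_read: int = 0
    paired: bool = False
    seed: int = 0

    @classmethod
    def from_json(cls, text: str) -> "FixtureSpec":
        data = json.loads(text)
        if "adapter" in data and data["adapter"] is not None:
            ad = data["adapter"]
            pos = ad.get("position", 20)
            if isinstance(pos, list):
                pos = tuple(pos)
            data["adapter"] = AdapterSpec(
                sequence=ad.get("sequence", ILLUMINA_ADAPTER),
                position=pos,
                fraction=ad.get("fraction", 0.5),
            )
        for key in ("read_length", "low_band", "high_band"):
            if isinstance(data.get(key), list):
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class GeneratedFixture:
    r1_path: str
    r2_path: Optional[str]
    sidecar_path: str
    truth: pd.DataFrame


def _validate(spec: FixtureSpec) -> QualityEncoding:
    if spec.encoding not in ENCODINGS:
        raise ConfigError(f"unknown encoding {spec.encoding!r}")
    enc = ENCODINGS[spec.encoding]
    min_len = spec.read_length if isinstance(spec.read_length, int) else spec.read_length[0]
    if spec.adapter is not None:
        pos = spec.adapter.position
        lo = pos if isinstance(pos, int) else pos[0]
        if len(spec.adapter.sequence) > min_len or lo >= min_len:
            raise ConfigError("adapter does not fit inside the shortest read")
    if not 0.0 <= spec.f_low <= 1.0:
        raise ConfigError("f_low must be in [0, 1]")
    return enc


def _scrub_spurious_adapter(seq: np.ndarray, adapter: str, keep_pos: int) -> None:
    """Deterministically mutate bases so the adapter (exact match, 3'
    partial overlap of >= 5 bases allowed) occurs nowhere left of
    ``keep_pos`` (-1: nowhere at all). Keeps sidecar adapter positions
    the unique leftmost match a trimmer will find."""
    n = len(seq)
    limit = keep_pos if keep_pos >= 0 else n
    changed = True
    while changed:
        changed = False
        for p in range(min(limit, n - 4)):
            aligned = min(len(adapter), n - p)
            if aligned < 5:
                break
            if "".join(seq[p : p + aligned]) == adapter[:aligned]:
                seq[p] = "A" if adapter[0] != "A" else "C"
                changed = True
                break


def _phred_of(score: int, enc: QualityEncoding) -> float:
    if enc.is_solexa:
        return solexa_to_phred(score)
    return float(score)


def generate(spec: FixtureSpec, outdir: str, prefix: str = "synth") -> GeneratedFixture:
    """Write FASTQ file(s) and the ground-truth sidecar; returns paths
    plus the truth table as a DataFrame."""
    enc = _validate(spec)
    os.makedirs(outdir, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    bases = np.array(list("ACGT"))
    mates = (1, 2) if spec.paired else (1,)
    handles = {}
    r1_path = os.path.join(outdir, f"{prefix}_R1.fastq")
    handles[1] = open(r1_path, "wt", encoding="ascii", newline="")
    r2_path = None
    if spec.paired:
        r2_path = os.path.join(outdir, f"{prefix}_R2.fastq")
        handles[2] = open(r2_path, "wt", encoding="ascii", newline="")

    truth_rows = []
    try:
        for i in range(spec.n_reads):
            for mate in mates:
                if isinstance(spec.read_length, int):
                    length = spec.read_length
                else:
                    length = int(rng.integers(spec.read_length[0], spec.read_length[1] + 1))
                seq = rng.choice(bases, size=length)

                low = bool(rng.random() < spec.f_low)
                if (
                    i == 0 and mate == 1 and spec.f_low > 0
                    and enc.ascii_offset == 33
                ):
                    low = True  # keep offset-33 fixtures decidable
                band = spec.low_band if low else spec.high_band
                scores = rng.integers(band[0], band[1] + 1, size=length)

                adapter_pos = -1
                if spec.adapter is not None:
                    ad = spec.adapter.sequence
                    if rng.random() < spec.adapter.fraction:
                        pos = spec.adapter.position
                        if not isinstance(pos, int):
                            pos = int(rng.integers(pos[0], pos[1] + 1))
                        end = min(pos + len(ad), length)
                        seq[pos:end] = list(ad[: end - pos])
                        adapter_pos = pos
                    _scrub_spurious_adapter(seq, ad, adapter_pos)

                n_count = 0
                if spec.n_per_read > 0 and rng.random() < spec.n_fraction:
                    positions = rng.choice(
                        length, size=min(spec.n_per_read, length), replace=False
                    )
                    seq[positions] = "N"
                    n_count = len(positions)

                sequence = "".join(seq)
                n_count = sequence.count("N")
                quality = "".join(chr(int(s) + enc.ascii_offset) for s in scores)
                phreds = [_phred_of(int(s), enc) for s in scores]
                mean_q = sum(phreds) / length
                kept = adapter_pos if adapter_pos >= 0 else length
                mean_q_kept = sum(phreds[:kept]) / kept if kept > 0 else float("nan")

                suffix = f"/{mate}" if spec.paired else ""
                read_id = f"{prefix}_{i:06d}{suffix}"
                handles[mate].write(f"@{read_id}\n{sequence}\n+\n{quality}\n")
                truth_rows.append(
                    {
                        "read_id": read_id,
                        "mate": mate,
                        "length": length,
                        "low_stratum": int(low),
                        "mean_quality": mean_q,
                        "mean_quality_kept": mean_q_kept,
                        "adapter_pos": adapter_pos,
                        "n_count": n_count,
                    }
                )
    finally:
        for fh in handles.values():
            fh.close()

    truth = pd.DataFrame(truth_rows)
    sidecar_path = os.path.join(outdir, f"{prefix}_truth.tsv")
    truth.to_csv(sidecar_path, sep="\t", index=False, float_format="%.6f")
    return GeneratedFixture(r1_path, r2_path, sidecar_path, truth)
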