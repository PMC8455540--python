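"""Routing of mate-pair verdicts that preserves paired-file lockstep.

Cleaned R1 and R2 files must stay record-for-record synchronized, so a
pair survives only if both mates pass. By default a pair with exactly
one passing mate is dropped entirely (guaranteeing aligner-compatible
output); with ``keep_orphans`` the surviving mate is diverted to a
separate unpaired file instead.
"""

from __future__ import annotations

from dataclasses import dataclass

from .read_filters import ReadVerdict

ROUTINGS = ("both_pass", "both_drop", "orphan_r1", "orphan_r2")


@dataclass(frozen=True)
class PairOutcome:
    routing: str  # one of ROUTINGS
    v1: ReadVerdict
    v2: ReadVerdict


def resolve_pair(v1: ReadVerdict, v2: ReadVerdict, keep_orphans: bool = False) -> PairOutcome:
    """Combine two mate verdicts into a routing decision."""
    if v1.passed and v2.passed:
        return PairOutcome("both_pass", v1, v2)
    if v1.passed and keep_orphans:
        return PairOutcome("orphan_r1", v1, v2)
    if v2.passed and keep_orphans:
        return PairOutcome("orphan_r2", v1, v2)
    return PairOutcome("both_drop", v1, v2)
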