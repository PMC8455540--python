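# Methods

## Scope and model of the data

`htsqc` treats a sequencing sample as a stream of four-line FASTQ
records from an Illumina-class instrument: fixed alphabet {A, C, G, T,
N} (lowercase is uppercased on input; anything else is a fatal parse
error, since the base-composition statistics assume a five-letter
alphabet), a quality string of printable ASCII the same length as the
sequence, and — for paired-end data — two files whose records are in
lockstep order. Multi-line ("wrapped") FASTQ is rejected rather than
guessed at: quality lines may legitimately begin with `@`, which makes
wrapped records ambiguous, and Illumina writers emit strict four-line
records. Gzip input is recognised by the two-byte magic number, never
by filename, so misnamed files behave correctly; gzip output is written
with a zeroed timestamp so repeated runs are byte-identical.

## Quality encodings

Four variants are supported: `sanger_illumina18` (offset 33), `solexa`
(offset-64 log-odds), `illumina13` and `illumina15` (offset 64).
Detection takes the minimum ASCII code *m* over the quality strings of
up to 100,000 reads (a bounded first pass keeps detection streaming and
deterministic) and applies the classical range rule: *m* < 59 → Sanger;
59 ≤ *m* < 64 → Solexa; 64 ≤ *m* < 66 → Illumina 1.3; *m* ≥ 66 →
Illumina 1.5. Data whose characters all fall in 66–74 is genuinely
ambiguous (it could be uniformly high-quality offset-33 data); the
min-rule answer is returned with a warning, and `--qual-format` forces
an encoding for such inputs. The detected encoding is applied to the
whole file; a later character below the assumed offset is a fatal error
rather than a re-detection trigger, preserving single-pass semantics.
Solexa scores *s* (legal down to −5) are converted to Phred by
*Q* = 10·log₁₀(10^(s/10) + 1) and kept as real numbers.

For paired input the detection sample covers both mates, so the two
files cannot be assigned different encodings.

## Trimming

**Adapters.** Matching is a Hamming-distance scan: for each read
position (left to right) each adapter (in user order) is tested with
mismatch budget ⌊f·L⌋, where f is `--adapter-mismatch` (default 0) and
L the aligned length; a partial match hanging off the 3′ end needs at
least 5 aligned bases; an N in the read always counts as a mismatch so
N-rich reads cannot match arbitrary adapters. The first hit — smallest
position, ties to the earlier adapter — wins, and the read is truncated
at the match start: adapter *and* downstream bases are removed, the
read-through interpretation. 5′ trimming and paired-overlap adapter
inference are out of scope.

**Quality.** 3′ trimming removes the maximal suffix in which every base
is below the fixed `--trim-qual` threshold. This suffix rule was chosen
over a sliding window because it is deterministic, order-independent
and idempotent, which the serial/parallel identity guarantee relies on.

## Filtering and accounting

Filters run on the post-trim read in a fixed order — length, then N
content, then mean quality — cheapest first, and the first failure is
the read's single recorded reason, which makes the per-reason tallies a
partition of the input. Rules:

* length: fail if shorter than max(`--min-len`, 1); the floor of 1
  means empty reads always fail, since zero-length records are invalid
  FASTQ output.
* N content: `--max-n` (count) or `--max-n-fraction`, mutually
  exclusive, both off by default.
* mean quality: fail if the arithmetic mean of per-base Phred scores is
  *strictly* below `--min-qual` (default 20); a read at exactly the
  threshold passes. The mean-per-read statistic (unweighted by length)
  is also what the summary reports as "average read quality".

A *trimmed* read is shortened but retained; a *filtered* read is
discarded — the two tallies are independent. Base conservation is
tracked so that raw bases = clean bases + original bases of discarded
reads + bases trimmed from retained reads; the test suite asserts this
identity per run and after chunk merging.

**Paired-end.** Both mates are judged independently; `both_pass` pairs
are written at the same ordinal position of both cleaned files. By
default a pair with one failing mate is dropped entirely, which keeps
the cleaned files aligner-compatible; `--keep-orphans` diverts the
surviving mate to `<stem>_unpaired` files. Clean statistics accumulate
every *written* passing read (cleaned pairs plus orphans), so the
invariant clean reads = passing reads holds exactly for single-end runs
and for paired runs with orphans kept; with orphans dropped, the
routing tallies (`both_pass`, `both_drop`, `orphan_*`) carry the
reconciliation. Rejected reads saved with `--save-rejects` are written
in their original untrimmed form so the reject file is always valid
FASTQ.

## Parallel execution

The input (decompressed to a temporary plain file if gzipped, since
gzip streams are not byte-seekable) is split into at most `--cpus`
contiguous byte ranges that start on record boundaries. The boundary
search seeks to an approximate offset and scans for a line starting `@`
whose following three lines parse as a record with a `+` separator —
the look-ahead rejects quality lines that begin with `@`. Paired mate
files are split at the same record indices. Encoding detection is
hoisted out of the workers (a chunk-local minimum could differ and
break serial/parallel equivalence). Each worker writes plain-text part
files; the parent concatenates them in chunk order through the same
writer used by the serial path and merges chunk statistics, which are
exact sums/min/max. Worker failure aborts the run and removes partial
final outputs; the per-run working directory is deleted in all cases,
idempotently.

Floating-point aggregates (sums of per-read means) are added in a
different order serially vs. chunk-merged; summary and table floats are
written rounded (4 and 6 decimals) so the reports are insensitive to
last-ulp differences, and byte-identity of all artifacts is asserted in
the acceptance tests at 1, 2 and 4 workers.

## Reports

Per sample: a field/value summary (encoding, read/base counts before
and after, min/max/mean lengths, mean read quality, per-reason fail
counts, trimmed-read and trimmed-base counts) and four raw-vs-clean
figures with tab-separated backing tables — per-position mean quality,
per-read mean-quality histogram (bin = floor of the mean, clamped to
0–60), per-read GC histogram (bin = round-half-up percent; N is
excluded from numerator and denominator, and reads with no called bases
are excluded from the histogram and counted separately), and
per-position base composition. Histogram percentages are normalised to
the reads they contain, so each series sums to 100 up to rounding. The
tables, not the PNGs, are the numeric contract.

## Synthetic data generator

`htsqc synth` (module `htsqc.synth`) emulates exactly the artifacts the
pipeline targets, with per-read ground truth in a sidecar table:

* **Quality**: a two-band mixture — with probability `f_low` a read
  draws every base quality uniformly from `low_band` (default 2–15),
  otherwise from `high_band` (default 25–40). Under the default Q20
  mean filter, low-band reads always fail and high-band reads always
  pass, so `f_low` is the expected failure rate and per-read outcomes
  are decidable from the sidecar. For offset-33 specs with `f_low` > 0
  the first read is pinned to the low band so detection is always
  decidable; offset-64 specs emit no character below their offset by
  construction.
* **Adapter read-through**: a given fraction of reads have the adapter
  written over their bases at a known (fixed or uniformly sampled)
  position. Sequences are deterministically scrubbed of *unintended*
  exact adapter occurrences (including ≥ 5-base 3′ prefixes) left of
  the intended site, so the sidecar position is the unique leftmost
  match a trimmer can find — without this, roughly 0.1% of random
  100-mers would carry a spurious 3′ match and ground-truth comparisons
  would not be exact.
* **N spikes**: a fraction of reads receive a fixed number of Ns at
  random positions; the sidecar records the realised count.
* **Pairing**: mates share ids (`/1`, `/2`) and draw their quality
  strata independently, giving independent mate-failure as the pair
  policy tests require.

One `numpy` generator seeded from the spec drives all draws; identical
spec + seed yields byte-identical files. The generator does not emulate
platform error profiles, position-dependent quality decay, duplicate
reads or biased base composition — so passing tests demonstrate the
pipeline's bookkeeping and guarantees, not its behaviour on every
pathology of real data.

## Problem sizes and numerical choices

Tests and the acceptance script use fixtures of 300–10,000 reads —
large enough that every code path (all four encodings, both strata,
contaminated and clean reads, all chunk counts) is exercised and
binomial fractions converge, while the whole suite runs in well under a
minute. Histogram bin width is 1 unit (percent or Phred) with
round-half-up for GC and floor for quality, chosen once for
determinism. Exit codes: 0 success, 1 any sample failed, 2 usage error.

## Known limitations

No duplicate-read removal (deliberately: it interacts with abundance
estimation), no sliding-window quality trimming, no poly-A/G tail
trimming, no UMI handling, no interleaved or SAM/BAM input, no
multi-node scheduling (batch parallelism is per-sample within one
machine). Ambiguous uniformly-high-quality files require a forced
encoding. Adapter matching is Hamming-based; indel-tolerant alignment
is out of scope.
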