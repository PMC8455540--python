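"""QC statistics: per-read bookkeeping, exact merge algebra, summary
fields and report-table normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from htsqc import (
    ENCODINGS,
    QCStats,
    SampleResult,
    SequenceRecord,
    Tallies,
    gc_percent,
    merge_stats,
    render_plots,
    render_summary,
)
from htsqc.qc_stats import render_tables

SANGER = ENCODINGS["sanger_illumina18"]


@pytest.mark.parametrize(
    "seq,expected",
    [("GGCC", 100.0), ("ATGC", 50.0), ("GCNN", 100.0), ("AT", 0.0)],
)
def test_gc_percent(seq, expected):
    assert gc_percent(seq) == expected


def test_gc_percent_undefined_without_called_bases():
    assert gc_percent("NNN") is None
    assert gc_percent("") is None


def _stats_of(reads):
    s = QCStats()
    for seq, qual in reads:
        rec = SequenceRecord("r", seq, qual)
        s.update_read(rec, [float(ord(c) - 33) for c in qual])
    return s


def _stats_equal(a: QCStats, b: QCStats) -> bool:
    if (a.n_reads, a.n_bases, a.min_len, a.max_len, a.sum_len,
            a.n_no_called_bases) != (
            b.n_reads, b.n_bases, b.min_len, b.max_len, b.sum_len,
            b.n_no_called_bases):
        return False
    if abs(a.sum_mean_quality - b.sum_mean_quality) > 1e-9:
        return False
    n = max(a.pos_count.shape[0], b.pos_count.shape[0])

    def pad(x, n, two_d=False):
        if two_d:
            out = np.zeros((5, n))
            out[:, : x.shape[1]] = x
        else:
            out = np.zeros(n)
            out[: x.shape[0]] = x
        return out

    return (
        np.array_equal(pad(a.pos_count, n), pad(b.pos_count, n))
        and np.allclose(pad(a.pos_quality_sum, n), pad(b.pos_quality_sum, n))
        and np.array_equal(pad(a.base_counts, n, True), pad(b.base_counts, n, True))
        and np.array_equal(a.gc_histogram, b.gc_histogram)
        and np.array_equal(a.read_quality_histogram, b.read_quality_histogram)
    )


class TestUpdate:
    def test_single_read_bookkeeping(self):
        s = _stats_of([("ACGT", "IIII")])  # Q40, GC 50%
        assert s.n_reads == 1 and s.n_bases == 4
        assert s.gc_histogram[50] == 1
        assert s.read_quality_histogram[40] == 1
        assert s.min_len == s.max_len == 4

    def test_length_extremes_and_mean(self):
        s = _stats_of([("ACG", "III"), ("ACGTA", "IIIII")])
        assert (s.min_len, s.max_len, s.mean_length) == (3, 5, 4.0)

    def test_gc_bin_rounds_half_up(self):
        s = _stats_of([("GAA", "III")])  # 33.33 -> bin 33
        assert s.gc_histogram[33] == 1
        s = _stats_of([("GA", "II")])  # 50.0 -> bin 50
        assert s.gc_histogram[50] == 1
        s = _stats_of([("GGGA", "IIII")])  # 75.0 -> 75
        assert s.gc_histogram[75] == 1
        s = _stats_of([("GGGGGA", "IIIIII")])  # 83.33 -> 83
        assert s.gc_histogram[83] == 1

    def test_all_n_read_counted_separately(self):
        s = _stats_of([("NNN", "III")])
        assert s.gc_histogram.sum() == 0
        assert s.n_no_called_bases == 1
        assert s.n_reads == 1

    def test_histograms_account_for_every_read(self):
        rng = np.random.default_rng(3)
        reads = []
        for _ in range(200):
            n = int(rng.integers(5, 40))
            seq = "".join(rng.choice(list("ACGTN"), n))
            qual = "".join(chr(33 + int(q)) for q in rng.integers(0, 41, n))
            reads.append((seq, qual))
        s = _stats_of(reads)
        assert s.read_quality_histogram.sum() == s.n_reads
        assert s.gc_histogram.sum() + s.n_no_called_bases == s.n_reads
        assert s.base_counts.sum(axis=0).tolist() == s.pos_count.tolist()

    def test_order_independence_of_aggregates(self):
        rng = np.random.default_rng(5)
        reads = [
            ("".join(rng.choice(list("ACGT"), 20)),
             "".join(chr(33 + int(q)) for q in rng.integers(0, 41, 20)))
            for _ in range(100)
        ]
        a = _stats_of(reads)
        b = _stats_of(list(reversed(reads)))
        assert _stats_equal(a, b)


reads_strategy = st.lists(
    st.tuples(
        st.text(alphabet="ACGTN", min_size=1, max_size=30),
    ).map(lambda t: (t[0], "I" * len(t[0]))),
    max_size=30,
)


class TestMergeAlgebra:
    @given(reads_strategy, reads_strategy)
    @settings(deadline=None, max_examples=20, derandomize=True)
    def test_commutative_and_equals_concatenation(self, ra, rb):
        a, b = _stats_of(ra), _stats_of(rb)
        assert _stats_equal(merge_stats(a, b), merge_stats(b, a))
        assert _stats_equal(merge_stats(a, b), _stats_of(ra + rb))

    @given(reads_strategy, reads_strategy, reads_strategy)
    @settings(deadline=None, max_examples=20, derandomize=True)
    def test_associative(self, ra, rb, rc):
        a, b, c = (_stats_of(r) for r in (ra, rb, rc))
        assert _stats_equal(
            merge_stats(merge_stats(a, b), c), merge_stats(a, merge_stats(b, c))
        )

    @given(reads_strategy)
    @settings(deadline=None, max_examples=20, derandomize=True)
    def test_empty_is_identity(self, ra):
        a = _stats_of(ra)
        assert _stats_equal(merge_stats(a, QCStats()), a)
        assert _stats_equal(merge_stats(QCStats(), a), a)


def _sample_result(reads, name="s1"):
    stats = _stats_of(reads)
    tallies = Tallies(n_pass=len(reads))
    return SampleResult(name, {}, stats, stats, SANGER, tallies)


class TestRendering:
    def test_summary_fields_for_known_fixture(self, tmp_path):
        result = _sample_result([("ACGT", "IIII"), ("GGGGCC", "555555")])
        path = render_summary(result, str(tmp_path))
        table = dict(
            line.split("\t") for line in open(path).read().splitlines()[1:]
        )
        assert table["raw_reads"] == "2"
        assert table["raw_bases"] == "10"
        assert table["raw_min_length"] == "4"
        assert table["raw_max_length"] == "6"
        assert table["raw_mean_length"] == "5.0000"
        assert table["raw_mean_read_quality"] == "30.0000"  # (40+20)/2
        assert table["sequence_quality_format"] == "sanger_illumina18"

    def test_empty_sample_reports_na_lengths(self, tmp_path):
        result = SampleResult("empty", {}, QCStats(), QCStats(), SANGER, Tallies())
        path = render_summary(result, str(tmp_path))
        text = open(path).read()
        assert "raw_min_length\tNA" in text
        assert "raw_reads\t0" in text

    def test_tables_normalize_to_100_percent(self, tmp_path):
        rng = np.random.default_rng(9)
        reads = [
            ("".join(rng.choice(list("ACGTN"), 30)),
             "".join(chr(33 + int(q)) for q in rng.integers(0, 41, 30)))
            for _ in range(150)
        ]
        result = _sample_result(reads)
        paths = render_tables(result, str(tmp_path))
        qh = pd.read_csv(paths["read_quality_hist"], sep="\t")
        assert qh["raw_percent"].sum() == pytest.approx(100.0, abs=0.1)
        gh = pd.read_csv(paths["gc_hist"], sep="\t")
        assert gh["raw_percent"].sum() == pytest.approx(100.0, abs=0.1)
        bc = pd.read_csv(paths["base_composition"], sep="\t")
        base_cols = [c for c in bc.columns if c.startswith("raw_pct_")]
        sums = bc[base_cols].sum(axis=1)
        assert np.allclose(sums, 100.0, atol=0.1)

    def test_constant_quality_gives_constant_position_line(self, tmp_path):
        result = _sample_result([("ACGT", "IIII")] * 5)
        paths = render_plots(result, str(tmp_path))
        pq = pd.read_csv(paths["per_position_quality"], sep="\t")
        assert (pq["raw_mean_quality"] == 40.0).all()
        for key in ("per_position_quality_png", "read_quality_hist_png",
                    "gc_hist_png", "base_composition_png"):
            assert (tmp_path / paths[key].split("/")[-1]).exists()
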