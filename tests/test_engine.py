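"""End-to-end serial runs, serial/parallel byte-identity, pair
synchronization, conservation accounting and intermediate cleanup."""

import os

import pytest

from htsqc import (
    AdapterSet,
    FilterConfig,
    FixtureSpec,
    RunOptions,
    cleanup_intermediates,
    generate,
    run_parallel,
    run_serial,
)
from htsqc.fastq_io import pair_key, read_fastq_path, read_paired_paths
from htsqc.synth import AdapterSpec

from conftest import fastq_lines, oracle_evaluate, parse_fastq_naive, write_lines


def summary_dict(path):
    return dict(line.split("\t") for line in open(path).read().splitlines()[1:])


class TestRunSerial:
    def test_empty_input(self, tmp_path):
        path = write_lines(tmp_path / "empty.fastq", [])
        res = run_serial(path, out_dir=str(tmp_path / "out"))
        assert res.tallies.n_reads == 0
        assert os.path.exists(res.output_paths["clean1"])
        assert open(res.output_paths["clean1"]).read() == ""

    def test_pass_count_matches_oracle(self, tmp_path):
        fx = generate(FixtureSpec(n_reads=1000, f_low=0.3, seed=7), str(tmp_path))
        res = run_serial(fx.r1_path, out_dir=str(tmp_path / "out"))
        expected_pass = sum(
            1
            for rid, seq, qual in parse_fastq_naive(fx.r1_path)
            if oracle_evaluate(seq, qual)[0] == "pass"
        )
        assert res.tallies.n_pass == expected_pass
        assert res.stats_clean.n_reads == expected_pass
        # cleaned file on disk agrees with the tally
        assert len(list(read_fastq_path(res.output_paths["clean1"]))) == expected_pass

    def test_deterministic_reruns_are_byte_identical(self, tmp_path):
        fx = generate(FixtureSpec(n_reads=200, f_low=0.2, seed=3), str(tmp_path))
        r1 = run_serial(fx.r1_path, out_dir=str(tmp_path / "o1"))
        r2 = run_serial(fx.r1_path, out_dir=str(tmp_path / "o2"))
        a = open(r1.output_paths["clean1"], "rb").read()
        b = open(r2.output_paths["clean1"], "rb").read()
        assert a == b

    def test_fasta_output_projects_cleaned_fastq(self, tmp_path):
        fx = generate(FixtureSpec(n_reads=100, f_low=0.4, seed=5), str(tmp_path))
        res_fq = run_serial(fx.r1_path, out_dir=str(tmp_path / "fq"))
        res_fa = run_serial(
            fx.r1_path,
            out_dir=str(tmp_path / "fa"),
            options=RunOptions(fasta_out=True),
        )
        fq_seqs = [r.sequence for r in read_fastq_path(res_fq.output_paths["clean1"])]
        fa_lines = open(res_fa.output_paths["clean1"]).read().splitlines()
        fa_seqs = [fa_lines[i + 1] for i in range(0, len(fa_lines), 2)]
        assert fa_seqs == fq_seqs

    def test_save_rejects_holds_original_reads(self, tmp_path):
        fx = generate(FixtureSpec(n_reads=100, f_low=0.5, seed=9), str(tmp_path))
        res = run_serial(
            fx.r1_path,
            out_dir=str(tmp_path / "out"),
            options=RunOptions(save_rejects=True),
        )
        rejects = list(read_fastq_path(res.output_paths["rejects"]))
        assert len(rejects) == res.tallies.n_fail
        raw = {r.read_id: r for r in read_fastq_path(fx.r1_path)}
        assert all(raw[r.read_id] == r for r in rejects)

    def test_conservation_reads_and_bases(self, tmp_path):
        fx = generate(
            FixtureSpec(
                n_reads=500,
                f_low=0.3,
                adapter=AdapterSpec(position=(10, 90), fraction=0.3),
                seed=13,
            ),
            str(tmp_path),
        )
        config = FilterConfig(
            adapters=AdapterSet(("AGATCGGAAGAGC",)), trim_quality_threshold=10
        )
        res = run_serial(fx.r1_path, config=config, out_dir=str(tmp_path / "out"))
        t = res.tallies
        assert res.stats_raw.n_reads == t.n_pass + t.n_fail
        assert res.stats_clean.n_reads == t.n_pass
        assert res.stats_raw.n_bases == (
            res.stats_clean.n_bases
            + t.rejected_bases
            + t.adapter_bases_removed
            + t.quality_bases_removed
        )


class TestSerialParallelEquivalence:
    @pytest.mark.parametrize("n_cpus", [1, 2, 4])
    def test_single_end_outputs_byte_identical(self, tmp_path, n_cpus):
        fx = generate(
            FixtureSpec(
                n_reads=2000,
                f_low=0.3,
                adapter=AdapterSpec(position=(10, 90), fraction=0.2),
                seed=21,
            ),
            str(tmp_path),
        )
        config = FilterConfig(adapters=AdapterSet(("AGATCGGAAGAGC",)))
        opts = RunOptions(save_rejects=True, make_plots=False)
        serial = run_serial(fx.r1_path, config=config,
                            out_dir=str(tmp_path / "ser"), options=opts)
        par = run_parallel(fx.r1_path, config=config,
                           out_dir=str(tmp_path / f"par{n_cpus}"),
                           options=opts, n_cpus=n_cpus)
        for key in ("clean1", "rejects", "summary"):
            a = open(serial.output_paths[key], "rb").read()
            b = open(par.output_paths[key], "rb").read()
            assert a == b, f"{key} differs at n_cpus={n_cpus}"

    def test_paired_chunks_stay_synchronized(self, tmp_path):
        fx = generate(
            FixtureSpec(n_reads=900, f_low=0.3, paired=True, seed=17), str(tmp_path)
        )
        par = run_parallel(fx.r1_path, fx.r2_path,
                           out_dir=str(tmp_path / "par"), n_cpus=3)
        ser = run_serial(fx.r1_path, fx.r2_path, out_dir=str(tmp_path / "ser"))
        for key in ("clean1", "clean2", "summary"):
            assert (
                open(par.output_paths[key], "rb").read()
                == open(ser.output_paths[key], "rb").read()
            )
        pairs = list(
            read_paired_paths(par.output_paths["clean1"], par.output_paths["clean2"])
        )
        assert len(pairs) == par.tallies.both_pass

    def test_gzip_input_and_output(self, tmp_path):
        import gzip

        fx = generate(FixtureSpec(n_reads=300, f_low=0.3, seed=29), str(tmp_path))
        gz_in = str(tmp_path / "in.fastq.gz")
        with open(fx.r1_path, "rb") as src, open(gz_in, "wb") as dst:
            dst.write(gzip.compress(src.read()))
        opts = RunOptions(gzip_out=True, make_plots=False)
        ser = run_serial(gz_in, out_dir=str(tmp_path / "ser"), options=opts)
        par = run_parallel(gz_in, out_dir=str(tmp_path / "par"), options=opts, n_cpus=2)
        recs_s = list(read_fastq_path(ser.output_paths["clean1"]))
        recs_p = list(read_fastq_path(par.output_paths["clean1"]))
        assert recs_s == recs_p
        plain = run_serial(fx.r1_path, out_dir=str(tmp_path / "plain"))
        assert recs_s == list(read_fastq_path(plain.output_paths["clean1"]))


class TestPairPolicyEndToEnd:
    def _run(self, tmp_path, keep_orphans):
        fx = generate(
            FixtureSpec(n_reads=600, f_low=0.3, paired=True, seed=31), str(tmp_path)
        )
        opts = RunOptions(keep_orphans=keep_orphans, make_plots=False)
        out = str(tmp_path / ("keep" if keep_orphans else "drop"))
        return fx, run_serial(fx.r1_path, fx.r2_path, out_dir=out, options=opts)

    def test_cleaned_files_stay_in_lockstep(self, tmp_path):
        _, res = self._run(tmp_path, keep_orphans=False)
        r1 = list(read_fastq_path(res.output_paths["clean1"]))
        r2 = list(read_fastq_path(res.output_paths["clean2"]))
        assert len(r1) == len(r2) == res.tallies.both_pass
        for a, b in zip(r1, r2):
            assert pair_key(a.read_id) == pair_key(b.read_id)

    def test_orphan_counts_reconcile_with_pass_tallies(self, tmp_path):
        _, res = self._run(tmp_path, keep_orphans=True)
        t = res.tallies
        orphans1 = len(list(read_fastq_path(res.output_paths["unpaired1"])))
        orphans2 = len(list(read_fastq_path(res.output_paths["unpaired2"])))
        assert orphans1 == t.orphan_r1
        assert orphans2 == t.orphan_r2
        assert t.n_pass == 2 * t.both_pass + t.orphan_r1 + t.orphan_r2
        # with orphans kept, every passing read is written somewhere
        assert res.stats_clean.n_reads == t.n_pass


class TestCleanup:
    def test_no_intermediates_after_successful_run(self, tmp_path):
        fx = generate(FixtureSpec(n_reads=200, f_low=0.2, seed=37), str(tmp_path))
        out = tmp_path / "out"
        run_parallel(fx.r1_path, out_dir=str(out), n_cpus=2,
                     options=RunOptions(make_plots=False))
        leftovers = [p for p in out.iterdir() if p.is_dir() or "part" in p.name]
        assert leftovers == []

    def test_failed_run_removes_partials(self, tmp_path):
        bad = write_lines(
            tmp_path / "bad.fastq",
            fastq_lines([("r1", "ACGT", "IIII")]) + ["@r2", "ACGT", "+"],
        )
        out = tmp_path / "out"
        with pytest.raises(Exception):
            run_parallel(bad, out_dir=str(out), n_cpus=2)
        assert not any("part" in p.name or p.is_dir() for p in out.iterdir())

    def test_cleanup_is_idempotent(self, tmp_path):
        d = tmp_path / "work"
        d.mkdir()
        (d / "x_part").write_text("x")
        cleanup_intermediates(str(d))
        cleanup_intermediates(str(d))  # second call must not raise
        assert not d.exists()
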