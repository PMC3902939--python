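import io
import random

import pytest
from hypothesis import given, settings, strategies as st

from selexevo._sequtils import revcomp
from selexevo.pool_io_qc import (
    BarcodeSpec,
    ConfigError,
    FlankNotFoundError,
    PoolTable,
    RawRead,
    collapse_unique,
    demultiplex,
    load_barcode_config,
    phred_filter,
    read_fastq,
    trim_flanks,
    trim_pool,
    write_fastq,
)
from selexevo.selexsim import PhredModel, default_barcodes, sequence_pool

import numpy as np


def _read(bases: str, q: int = 30, name: str = "r") -> RawRead:
    return RawRead(name, bases, tuple([q] * len(bases)))


def _spec(label="r1", fwd_bc="GATCCA", rev_bc="TTGACC") -> BarcodeSpec:
    return BarcodeSpec(label, fwd_bc, rev_bc, "GGAGCTC", "GTCCGTT")


class TestDemultiplex:
    def test_exact_hexamer_assignment(self):
        spec = _spec("r7")
        read = _read(spec.fwd_barcode + "ACGTACGT" + revcomp(spec.rev_barcode))
        result = demultiplex([read], [spec])
        assert [r.identifier for r in result.assigned["r7"]] == ["r"]
        assert result.n_unassigned == 0

    def test_unknown_barcode_goes_unassigned(self):
        read = _read("CCCCCC" + "ACGTACGT" + "CCCCCC")
        result = demultiplex([read], [_spec()])
        assert result.assigned["r1"] == []
        assert result.n_unassigned == 1

    def test_duplicate_barcode_pair_rejected(self):
        with pytest.raises(ConfigError):
            demultiplex([], [_spec("a"), _spec("b")])

    def test_read_conservation(self):
        rng = random.Random(5)
        specs = [_spec("r1"), _spec("r2", fwd_bc="AAAAAA", rev_bc="CCGGTT")]
        reads = [
            _read("".join(rng.choice("ACGT") for _ in range(30)), name=f"x{i}")
            for i in range(50)
        ]
        result = demultiplex(reads, specs)
        assert result.n_assigned + result.n_unassigned == len(reads)

    def test_simulated_errorfree_reads_all_assigned(self):
        """1000 reads from 3 rounds with error-free barcodes -> 0 unassigned."""
        specs = default_barcodes(3)
        rng = np.random.default_rng(11)
        population = {"ACGTACGTACGTACGTACGT": 60, "TTTTGGGGCCCCAAAATTTT": 40}
        model = PhredModel(frac_low=0.0, apply_errors=False)
        reads = []
        for spec in specs:
            reads.extend(sequence_pool(population, 334, spec, model, rng))
        reads = reads[:1000]
        result = demultiplex(reads, list(specs))
        assert result.n_assigned == len(reads)
        assert result.n_unassigned == 0


class TestTrimFlanks:
    def test_exact_flanks_yield_insert(self):
        spec = _spec()
        insert = "ACGTACGTAC"
        read = _read(spec.fwd_flank + insert + spec.rev_flank)
        trimmed = trim_flanks(read, spec, max_mismatch=0)
        assert trimmed.bases == insert
        assert len(trimmed.quals) == len(insert)

    def test_one_substitution_within_budget(self):
        spec = _spec()
        flank = spec.fwd_flank
        mutated = flank[:7] + ("A" if flank[7] != "A" else "C") + flank[8:]
        read = _read(mutated + "ACGTACGTAC" + spec.rev_flank)
        assert trim_flanks(read, spec, max_mismatch=1).bases == "ACGTACGTAC"
        with pytest.raises(FlankNotFoundError):
            trim_flanks(read, spec, max_mismatch=0)

    def test_missing_reverse_flank_rejected(self):
        spec = _spec()
        read = _read(spec.fwd_flank + "ACGTACGTACACGTACGTAC")
        with pytest.raises(FlankNotFoundError):
            trim_flanks(read, spec, max_mismatch=0)

    def test_quals_trimmed_in_register(self):
        spec = _spec()
        insert = "ACGTA"
        full = spec.fwd_flank + insert + spec.rev_flank
        quals = tuple(range(len(full)))
        trimmed = trim_flanks(RawRead("r", full, quals), spec)
        lo = len(spec.fwd_flank)
        assert trimmed.quals == quals[lo:lo + len(insert)]

    def test_stream_accounting(self):
        spec = _spec()
        good = _read(spec.fwd_flank + "ACGT" + spec.rev_flank)
        bad = _read("ACGT" * 10)
        kept, rejected = trim_pool([good, bad, good], spec)
        assert len(kept) == 2 and rejected == 1


class TestPhredFilter:
    def test_all_high_quality_kept(self):
        kept, rejected = phred_filter([_read("ACGT", q=30)])
        assert len(kept) == 1 and rejected == 0

    def test_single_q19_base_removes_read(self):
        read = RawRead("r", "ACGT", (30, 30, 19, 30))
        kept, rejected = phred_filter([read], min_q=20)
        assert kept == [] and rejected == 1

    def test_boundary_q20_kept(self):
        read = RawRead("r", "ACGT", (20, 20, 20, 20))
        kept, _ = phred_filter([read], min_q=20)
        assert len(kept) == 1

    def test_n_bases_rejected(self):
        kept, rejected = phred_filter([_read("ACNT", q=40)])
        assert kept == [] and rejected == 1

    def test_against_independent_scan_of_500_reads(self):
        rng = random.Random(3)
        reads = [
            RawRead(
                f"r{i}",
                "".join(rng.choice("ACGT") for _ in range(20)),
                tuple(rng.randint(10, 40) for _ in range(20)),
            )
            for i in range(500)
        ]
        kept, rejected = phred_filter(reads, min_q=20)
        expected = sum(1 for r in reads if min(r.quals) >= 20)
        assert len(kept) == expected
        assert rejected == 500 - expected

    def test_idempotent(self):
        rng = random.Random(4)
        reads = [
            RawRead(
                f"r{i}",
                "".join(rng.choice("ACGT") for _ in range(10)),
                tuple(rng.randint(15, 40) for _ in range(10)),
            )
            for i in range(100)
        ]
        once, _ = phred_filter(reads)
        twice, rejected_again = phred_filter(once)
        assert twice == once and rejected_again == 0


class TestCollapseUnique:
    def test_small_example(self):
        pool = collapse_unique([_read("AAA"), _read("AAA"), _read("AAC")], "p")
        assert pool.entries == {"AAA": 2, "AAC": 1}
        assert pool.total_reads == 3 and pool.n_distinct == 2

    def test_all_identical(self):
        pool = collapse_unique([_read("ACGT") for _ in range(7)], "p")
        assert pool.entries == {"ACGT": 7}

    def test_empty_input_valid(self):
        pool = collapse_unique([], "p")
        assert pool.total_reads == 0 and pool.n_distinct == 0

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.text(alphabet="ACGT", min_size=1, max_size=8), max_size=60))
    def test_totals_conserve_reads_and_match_sort_count_oracle(self, seqs):
        pool = collapse_unique([_read(s, name=f"r{i}") for i, s in enumerate(seqs)], "p")
        assert pool.total_reads == len(seqs)
        oracle = {}
        for s in sorted(seqs):
            oracle[s] = oracle.get(s, 0) + 1
        assert pool.entries == oracle


class TestPoolTableIO:
    @settings(derandomize=True, max_examples=30)
    @given(
        st.dictionaries(
            st.text(alphabet="ACGT", min_size=1, max_size=12),
            st.integers(min_value=1, max_value=10**6),
            min_size=1,
            max_size=30,
        )
    )
    def test_tsv_round_trip_exact(self, entries):
        pool = PoolTable("p9", entries, pressure_annotation=2.5)
        buf = io.StringIO()
        pool.to_tsv(buf)
        buf.seek(0)
        back = PoolTable.from_tsv(buf)
        assert back.entries == pool.entries
        assert back.round_label == "p9"
        assert back.pressure_annotation == 2.5

    def test_fasta_export_has_counts(self):
        pool = PoolTable("p1", {"ACGT": 3, "GGGG": 1})
        buf = io.StringIO()
        pool.to_fasta(buf)
        text = buf.getvalue()
        assert ">p1:1 count=3\nACGT\n" in text

    def test_fastq_round_trip(self, tmp_path):
        reads = [RawRead("a", "ACGT", (30, 20, 40, 2)), RawRead("b", "GG", (1, 41))]
        path = tmp_path / "x.fastq"
        write_fastq(reads, path)
        assert list(read_fastq(path)) == reads


def test_barcode_config_yaml_round(tmp_path):
    path = tmp_path / "bc.yaml"
    path.write_text(
        "rounds:\n"
        "  - round_label: r1\n"
        "    fwd_barcode: AACCGG\n"
        "    rev_barcode: GGTTAA\n"
        "    fwd_primer: GGAGCTC\n"
        "    rev_primer: GTCCGTT\n"
    )
    specs = load_barcode_config(path)
    assert specs[0].round_label == "r1" and specs[0].fwd_barcode == "AACCGG"
    bad = tmp_path / "bad.yaml"
    bad.write_text("rounds:\n  - round_label: rX\n    fwd_barcode: TOOLONGBC\n")
    with pytest.raises(ConfigError):
        load_barcode_config(bad)
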