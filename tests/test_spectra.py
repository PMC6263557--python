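"""Spectra accumulation, pooling, merge, and matrix I/O."""

import numpy as np
import pytest

import mutspect as ms
from mutspect.spectra import (
    MatrixFormatError,
    PoolingError,
    accumulate,
    merge,
    read_matrix,
    write_matrix,
)
from mutspect.variants import SkipCounters, VariantRecord

from conftest import naive_accumulate, write_vcf


def random_matrix(n, seed):
    rng = np.random.default_rng(seed)
    return ms.SpectraMatrix(
        [f"s{i}" for i in range(n)], rng.integers(0, 50, size=(n, 96))
    )


class TestAccumulate:
    def test_single_record_hits_one_column(self, tmp_path):
        fasta, index = ms.random_genome(1, 100, seed=5, out_dir=tmp_path)
        # find a position whose context middle we can use directly
        pos = 50
        ctx = ms.fetch(index, "chr1", pos - 1, pos + 1)
        ref = ctx[1]
        alt = next(b for b in "ACGT" if b != ref)
        cls = ms.classify(ctx, ref, alt)
        rec = VariantRecord("chr1", pos, ref, alt, np.array([1, 2, 0]))
        M = accumulate(iter([rec]), index, ["a", "b", "c"])
        expected = np.zeros((3, 96), dtype=np.int64)
        expected[:, cls.index] = [1, 2, 0]
        assert np.array_equal(M.counts, expected)
        index.close()

    def test_empty_stream_all_zero(self, small_genome):
        _, index = small_genome
        M = accumulate(iter([]), index, ["a", "b"])
        assert M.counts.shape == (2, 96) and M.total() == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_naive_double_loop_oracle(self, tmp_path, seed):
        """Vectorized accumulation == brute-force per-record per-sample
        loop, integer-exact, on random fixtures."""
        fasta, index = ms.random_genome(1, 800, seed=200 + seed, out_dir=tmp_path)
        vcf, _ = ms.simulate_vcf(
            index, 20, 500, seed=seed, out_path=tmp_path / f"o{seed}.vcf"
        )
        roster, stream, _ = ms.stream_vcf(vcf)
        records = list(stream)
        M = accumulate(iter(records), index, roster)
        assert np.array_equal(M.counts, naive_accumulate(records, index, roster))
        index.close()

    def test_pooling_equals_posthoc_row_aggregation(self, tmp_path):
        fasta, index = ms.random_genome(1, 600, seed=33, out_dir=tmp_path)
        vcf, _ = ms.simulate_vcf(index, 20, 200, seed=3, out_path=tmp_path / "p.vcf")
        roster, stream, _ = ms.stream_vcf(vcf)
        pooling = {s: ("g1" if i < 12 else "g2") for i, s in enumerate(roster)}
        pooled = accumulate(stream, index, roster, pooling=pooling)
        roster2, stream2, _ = ms.stream_vcf(vcf)
        unpooled = accumulate(stream2, index, roster2)
        assert pooled.row_labels == ["g1", "g2"]
        assert np.array_equal(pooled.counts[0], unpooled.counts[:12].sum(axis=0))
        assert np.array_equal(pooled.counts[1], unpooled.counts[12:].sum(axis=0))
        index.close()

    def test_unmapped_sample_is_error_unless_passthrough(self, small_genome):
        _, index = small_genome
        with pytest.raises(PoolingError):
            accumulate(iter([]), index, ["a", "b"], pooling={"a": "g"})
        M = accumulate(
            iter([]), index, ["a", "b"], pooling={"a": "g"}, pool_passthrough=True
        )
        assert M.row_labels == ["g", "b"]

    def test_ref_mismatch_skipped_and_counted(self, small_genome):
        _, index = small_genome
        pos = 30
        ctx = ms.fetch(index, "chr1", pos - 1, pos + 1)
        wrong_ref = next(b for b in "ACGT" if b != ctx[1])
        alt = next(b for b in "ACGT" if b not in (wrong_ref,))
        rec = VariantRecord("chr1", pos, wrong_ref, alt, np.array([1]))
        counters = SkipCounters()
        M = accumulate(iter([rec]), index, ["a"], counters=counters)
        assert M.total() == 0
        assert counters.extra["ref_mismatch"] == 1

    def test_sequence_edge_skipped_and_counted(self, small_genome):
        _, index = small_genome
        ref = ms.fetch(index, "chr1", 1, 1)
        alt = next(b for b in "ACGT" if b != ref)
        rec = VariantRecord("chr1", 1, ref, alt, np.array([1]))
        counters = SkipCounters()
        M = accumulate(iter([rec]), index, ["a"], counters=counters)
        assert M.total() == 0 and counters.extra["sequence_edge"] == 1

    def test_conservation_and_order_invariance(self, tmp_path):
        """sum(M) + skipped dosages == total input dosage, and permuting
        record order leaves M unchanged."""
        fasta, index = ms.random_genome(1, 500, seed=77, out_dir=tmp_path)
        vcf, _ = ms.simulate_vcf(index, 10, 150, seed=8, out_path=tmp_path / "c.vcf")
        roster, stream, _ = ms.stream_vcf(vcf)
        records = list(stream)
        total_dosage = sum(int(r.dosages.sum()) for r in records)
        counters = SkipCounters()
        M = accumulate(iter(records), index, roster, counters=counters)
        skipped = sum(counters.extra.values())
        assert skipped == 0  # simulated records all classify
        assert M.total() == total_dosage
        rng = np.random.default_rng(0)
        perm = list(records)
        rng.shuffle(perm)
        M2 = accumulate(iter(perm), index, roster)
        assert M == M2
        index.close()

    def test_streaming_contract_one_record_alive(self, small_genome):
        """The accumulator must hold at most one record at a time: a
        generator that tracks outstanding records raises otherwise."""
        _, index = small_genome
        ref = ms.fetch(index, "chr1", 50, 50)
        alt = next(b for b in "ACGT" if b != ref)

        alive = {"n": 0}

        class Tracked(VariantRecord):
            def __del__(self):
                alive["n"] -= 1

        def gen():
            for _ in range(100):
                # only the record yielded last iteration may still be
                # referenced (the consumer's loop variable); anything more
                # means records are being buffered
                if alive["n"] > 1:
                    raise AssertionError("records are being buffered")
                alive["n"] += 1
                yield Tracked("chr1", 50, ref, alt, np.array([1]))

        M = accumulate(gen(), index, ["a"])
        assert M.total() == 100


class TestMerge:
    def test_identity_and_disjoint_block_stack(self):
        A = random_matrix(3, 1)
        B = random_matrix(2, 2)
        B.row_labels = ["t0", "t1"]
        assert merge([A]) == A
        stacked = merge([A, B])
        assert stacked.row_labels == A.row_labels + B.row_labels
        assert np.array_equal(stacked.counts, np.vstack([A.counts, B.counts]))

    def test_overlapping_labels_summed(self):
        A = random_matrix(3, 3)
        B = random_matrix(3, 4)  # same labels s0..s2
        out = merge([A, B])
        assert np.array_equal(out.counts, A.counts + B.counts)

    def test_split_by_chromosome_then_merge_equals_single_pass(self, tmp_path):
        """Per-chromosome accumulation + merge == whole-file accumulation."""
        fasta, index = ms.random_genome(3, 400, seed=55, out_dir=tmp_path)
        vcf, _ = ms.simulate_vcf(index, 8, 300, seed=12, out_path=tmp_path / "w.vcf")
        roster, stream, _ = ms.stream_vcf(vcf)
        records = list(stream)
        whole = accumulate(iter(records), index, roster)
        parts = [
            accumulate(
                iter([r for r in records if r.chrom == c]), index, roster
            )
            for c in ("chr1", "chr2", "chr3")
        ]
        assert merge(parts) == whole
        index.close()

    def test_merge_associative_commutative(self):
        ms_list = [random_matrix(2, s) for s in range(4)]
        a = merge([merge(ms_list[:2]), merge(ms_list[2:])])
        b = merge(ms_list)
        assert a == b
        rev = merge(ms_list[::-1])
        # same content regardless of order, up to row ordering
        assert sorted(rev.row_labels) == sorted(b.row_labels)
        for lbl in b.row_labels:
            ia, ib = rev.row_labels.index(lbl), b.row_labels.index(lbl)
            assert np.array_equal(rev.counts[ia], b.counts[ib])


class TestMatrixIO:
    def test_round_trip(self, tmp_path):
        M = random_matrix(5, 9)
        path = tmp_path / "m.tsv"
        write_matrix(M, path)
        assert read_matrix(path) == M

    def test_header_grammar_and_first_token(self, tmp_path):
        M = random_matrix(2, 1)
        path = tmp_path / "m.tsv"
        write_matrix(M, path)
        header = open(path).readline().rstrip("\n").split("\t")
        assert header[1] == "A[C>A]A"
        assert len(header) == 97

    def test_wrong_column_count_rejected(self, tmp_path):
        M = random_matrix(2, 1)
        path = tmp_path / "m.tsv"
        write_matrix(M, path)
        lines = open(path).read().splitlines()
        broken = tmp_path / "b.tsv"
        broken.write_text(
            "\n".join("\t".join(l.split("\t")[:-1]) for l in lines) + "\n"
        )
        with pytest.raises(MatrixFormatError):
            read_matrix(broken)

    def test_negative_counts_rejected(self):
        with pytest.raises(MatrixFormatError):
            ms.SpectraMatrix(["a"], -np.ones((1, 96), dtype=int))
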