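"""On-disk format: byte budgets, sorted merge semantics, index
construction, paired dual-keying, deletion, and integrity checking."""

import numpy as np
import pytest

from conftest import store_dataset
from hitdb import Alignment, BLOCK_RECORDS, SingleHit, build_index
from hitdb.hitcore import (
    INDEX_DTYPE,
    CorruptRecordError,
    HitArray,
    PairedHit,
    PairedHitArray,
)
from hitdb.synthgen import GenSpec, generate


def _files(aln, chrom, part):
    return {
        col: aln.path / f"{chrom}.{part}.{col}"
        for col in ("positions", "attrs", "weights", "index")
    }


class TestSingleEndWrites:
    def test_writes_are_position_sorted(self, make_alignment):
        aln = make_alignment()
        aln.append_single(1, [SingleHit(1, p, "+", 36) for p in (500, 100, 300)])
        assert aln.read_positions(1, "single").tolist() == [100, 300, 500]

    def test_append_merges_with_existing_records(self, make_alignment):
        aln = make_alignment()
        aln.append_single(1, [SingleHit(1, 100, "+", 36)])
        aln.append_single(1, [SingleHit(1, 50, "-", 36)])
        assert aln.read_positions(1, "single").tolist() == [50, 100]

    def test_byte_budget_4_2_4_per_record(self, make_alignment):
        """1000 single-end hits: 4000-byte positions, 2000-byte attrs,
        4000-byte weights, one 8-byte index entry per 1024 records."""
        aln = make_alignment()
        n = 1000
        rng = np.random.default_rng(0)
        hits = HitArray.from_fields(
            rng.integers(1, 10**6, n), rng.random(n) < 0.5, np.full(n, 36), np.ones(n)
        )
        aln.append_single(1, hits)
        f = _files(aln, 1, "single")
        assert f["positions"].stat().st_size == 4 * n
        assert f["attrs"].stat().st_size == 2 * n
        assert f["weights"].stat().st_size == 4 * n
        assert f["index"].stat().st_size == 8 * ((n + BLOCK_RECORDS - 1) // BLOCK_RECORDS)

    def test_write_is_order_insensitive_byte_identical(self, tmp_path):
        """Any permutation of a hit multiset serialises to identical bytes."""
        rng = np.random.default_rng(1)
        n = 500
        hits = HitArray.from_fields(
            rng.integers(1, 10**5, n), rng.random(n) < 0.5,
            rng.integers(20, 50, n), rng.random(n).astype(np.float32),
        )
        perm = rng.permutation(n)
        a = Alignment(tmp_path / "a", create=True)
        b = Alignment(tmp_path / "b", create=True)
        a.append_single(1, hits)
        b.append_single(1, hits.take(perm))
        for col in ("positions", "attrs", "weights", "index"):
            assert (a.path / f"1.single.{col}").read_bytes() == (
                b.path / f"1.single.{col}"
            ).read_bytes()

    def test_incremental_write_equals_single_write(self, tmp_path):
        ds = generate(GenSpec(seed=5, n_reads=400, n_chroms=1))
        hits = ds.hits_by_chrom[1]
        whole = Alignment(tmp_path / "w", create=True)
        split = Alignment(tmp_path / "s", create=True)
        whole.append_single(1, hits)
        split.append_single(1, hits.take(np.arange(0, 150)))
        split.append_single(1, hits.take(np.arange(150, 400)))
        for col in ("positions", "attrs", "weights", "index"):
            assert (whole.path / f"1.single.{col}").read_bytes() == (
                split.path / f"1.single.{col}"
            ).read_bytes()

    def test_little_endian_golden_bytes(self, make_alignment):
        """The serialised record layout is fixed: little-endian int32 pos,
        uint16 strand/length word (strand bit 15), float32 weight."""
        aln = make_alignment()
        aln.append_single(1, [SingleHit(1, 258, "-", 36, 1.0)])
        assert (aln.path / "1.single.positions").read_bytes() == b"\x02\x01\x00\x00"
        assert (aln.path / "1.single.attrs").read_bytes() == b"\x24\x80"  # 0x8024
        assert (aln.path / "1.single.weights").read_bytes() == b"\x00\x00\x80\x3f"
        assert (aln.path / "1.single.index").read_bytes() == (
            b"\x02\x01\x00\x00" + b"\x00\x00\x00\x00"
        )

    def test_weight_stored_at_float32_precision(self, make_alignment):
        aln = make_alignment()
        aln.append_single(1, [SingleHit(1, 10, "+", 36, 0.1)])
        got = aln.read_single(1)
        assert got.weight[0] == np.float32(0.1)

    def test_roundtrip_field_exact(self, make_alignment):
        ds = generate(GenSpec(seed=2, n_reads=300, n_chroms=1, weight_model="uniform"))
        aln = make_alignment()
        aln.append_single(1, ds.hits_by_chrom[1])
        got = aln.read_single(1)
        exp = ds.hits_by_chrom[1].sorted()
        assert np.array_equal(got.pos, exp.pos)
        assert np.array_equal(got.attrs, exp.attrs)
        assert np.array_equal(got.weight, exp.weight)

    def test_read_records_empty_range_and_bounds(self, make_alignment):
        aln = make_alignment()
        aln.append_single(1, [SingleHit(1, 10, "+", 36)])
        assert len(aln.read_single(1, 1, 1)) == 0
        with pytest.raises(IndexError):
            aln.read_single(1, 0, 2)


class TestBlockIndex:
    def test_empty_and_small_inputs(self):
        assert len(build_index(np.array([], dtype=np.int32))) == 0
        idx = build_index(np.arange(1, 1026, dtype=np.int32))  # 1025 records
        assert idx["offset"].tolist() == [0, 1024]
        assert idx["first"].tolist() == [1, 1025]

    def test_one_entry_per_block_with_correct_first_positions(self):
        pos = np.sort(np.random.default_rng(3).integers(1, 10**7, 5000)).astype(np.int32)
        idx = build_index(pos)
        assert len(idx) == -(-5000 // BLOCK_RECORDS)
        for k, entry in enumerate(idx):
            assert entry["offset"] == k * BLOCK_RECORDS
            assert entry["first"] == pos[k * BLOCK_RECORDS]
        assert idx.dtype.itemsize == 8

    def test_rejects_unsorted_positions(self):
        with pytest.raises(CorruptRecordError):
            build_index(np.array([5, 3, 9], dtype=np.int32))

    def test_capacity_arithmetic(self):
        """A 64 kb index file (8192 entries at 8 bytes) addresses
        8192 * 1024 = 8,388,608 records at 4 kb block granularity, and
        four times that at 16 kb."""
        entries_in_64kb = 65536 // INDEX_DTYPE.itemsize
        assert entries_in_64kb * BLOCK_RECORDS == 8_388_608
        assert entries_in_64kb * (4 * BLOCK_RECORDS) == 33_554_432
        assert entries_in_64kb * BLOCK_RECORDS >= 8_000_000
        assert entries_in_64kb * (4 * BLOCK_RECORDS) >= 32_000_000


class TestPairedStorage:
    def test_each_pair_stored_twice(self, make_alignment):
        aln = make_alignment()
        aln.append_paired([PairedHit(1, 100, "+", 36, 1.0, 1, 260, "-", 36)])
        assert aln.count(1, "pairedL") == 1
        assert aln.count(1, "pairedR") == 1
        left = aln.read_paired(1, "pairedL").to_pairs()[0]
        right = aln.read_paired(1, "pairedR").to_pairs()[0]
        assert right == left.flipped()

    def test_interchromosomal_routing(self, make_alignment):
        aln = make_alignment()
        aln.append_paired([PairedHit(1, 100, "+", 36, 1.0, 2, 900, "-", 36)])
        assert aln.count(1, "pairedL") == 1 and aln.count(1, "pairedR") == 0
        assert aln.count(2, "pairedR") == 1 and aln.count(2, "pairedL") == 0

    def test_partitions_bijective_under_anchor_swap(self, make_alignment):
        ds = generate(GenSpec(seed=7, n_reads=500, paired_fraction=1.0,
                              n_chroms=3, interchrom_fraction=0.2))
        aln = make_alignment()
        aln.append_paired(ds.pairs)
        left, right = [], []
        for c in aln.chroms():
            left += aln.read_paired(c, "pairedL").to_pairs()
            right += aln.read_paired(c, "pairedR").to_pairs()
        assert len(left) == len(right) == 500
        assert sorted(map(repr, (p.flipped() for p in right))) == sorted(map(repr, left))

    def test_paired_partition_sorted_by_keyed_side(self, make_alignment):
        ds = generate(GenSpec(seed=8, n_reads=200, paired_fraction=1.0))
        aln = make_alignment()
        aln.append_paired(ds.pairs)
        for c in aln.chroms():
            for part in ("pairedL", "pairedR"):
                pos = aln.read_positions(c, part)
                assert np.all(np.diff(pos) >= 0)


class TestDelete:
    def test_delete_single_leaves_paired_untouched(self, make_alignment):
        ds = generate(GenSpec(seed=9, n_reads=100, paired_fraction=0.5))
        aln = store_dataset(make_alignment(), ds)
        aln.delete(endedness="single")
        assert all(v["single"] == 0 for v in aln.chroms().values())
        total_paired = sum(v["pairedL"] for v in aln.chroms().values())
        assert total_paired == len(ds.pairs)

    def test_delete_is_idempotent(self, make_alignment):
        aln = make_alignment()
        aln.append_single(1, [SingleHit(1, 10, "+", 36)])
        aln.delete()
        assert aln.count(1) == 0
        aln.delete()  # second call is a no-op success
        assert aln.chroms() == {}


class TestVerify:
    def test_clean_store_has_no_problems(self, make_alignment):
        ds = generate(GenSpec(seed=10, n_reads=200, paired_fraction=0.3))
        aln = store_dataset(make_alignment(), ds)
        assert aln.verify() == []

    def test_detects_truncated_column(self, make_alignment):
        ds = generate(GenSpec(seed=10, n_reads=200))
        aln = store_dataset(make_alignment(), ds)
        f = aln.path / "1.single.weights"
        f.write_bytes(f.read_bytes()[:-4])
        assert any("weights" in p for p in aln.verify())

    def test_detects_unsorted_positions(self, make_alignment):
        ds = generate(GenSpec(seed=11, n_reads=100, n_chroms=1))
        aln = store_dataset(make_alignment(), ds)
        f = aln.path / "1.single.positions"
        pos = np.fromfile(f, dtype="<i4")
        pos[0], pos[-1] = pos[-1], pos[0]
        pos.tofile(f)
        assert any("not sorted" in p for p in aln.verify())

    def test_detects_stale_index(self, make_alignment):
        ds = generate(GenSpec(seed=12, n_reads=100, n_chroms=1))
        aln = store_dataset(make_alignment(), ds)
        f = aln.path / "1.single.index"
        idx = np.fromfile(f, dtype=INDEX_DTYPE)
        idx["first"] += 1
        idx.tofile(f)
        assert any("index" in p for p in aln.verify())
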