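"""Indexed queries against the brute-force oracle, filter semantics,
histogram conservation, and the record-decode (I/O) bound."""

import numpy as np
import pytest

from conftest import store_dataset
from hitdb import (
    BLOCK_RECORDS,
    HitFilter,
    QueryStats,
    Region,
    SingleHit,
    count_hits,
    get_hits,
    histogram,
    list_chromosomes,
    locate,
    sum_weights,
)
from hitdb.hitcore import INDEX_DTYPE
from hitdb.synthgen import GenSpec, generate


def _index(entries):
    return np.array(entries, dtype=INDEX_DTYPE)


class TestLocate:
    def test_binary_search_on_two_entries(self):
        idx = _index([(100, 0), (900, 1024)])
        assert locate(idx, 950) == 1024
        assert locate(idx, 900) == 1024
        assert locate(idx, 899) == 0

    def test_position_before_first_entry_clamps_to_zero(self):
        assert locate(_index([(100, 0)]), 50) == 0
        assert locate(_index([]), 50) == 0

    def test_no_hit_at_or_after_query_lies_before_returned_offset(self):
        rng = np.random.default_rng(0)
        pos = np.sort(rng.integers(1, 10**6, 5000)).astype(np.int32)
        from hitdb import build_index

        idx = build_index(pos)
        for s in rng.integers(1, 10**6, 50):
            off = locate(idx, int(s))
            assert not np.any(pos[:off] >= s)


class TestSelectionSemantics:
    def test_region_bounds_inclusive(self, make_alignment):
        aln = make_alignment()
        aln.append_single(1, [SingleHit(1, p, "+", 36) for p in (10, 20, 30)])
        got = get_hits(aln, Region(1, 15, 25))
        assert got.pos.tolist() == [20]
        assert get_hits(aln, Region(1, 20, 20)).pos.tolist() == [20]

    def test_selection_is_by_five_prime_position_not_span(self, make_alignment):
        """A minus-strand hit spanning into the region but whose 5' end
        (its stored position) lies outside is not returned."""
        aln = make_alignment()
        aln.append_single(1, [SingleHit(1, 150, "-", 100)])  # covers 51..150
        assert len(get_hits(aln, Region(1, 40, 120))) == 0
        assert len(get_hits(aln, Region(1, 120, 160))) == 1

    def test_minweight_threshold_is_inclusive(self, make_alignment):
        aln = make_alignment()
        aln.append_single(
            1, [SingleHit(1, 10 * i, "+", 36, w) for i, w in enumerate([0.5, 1.0, 2.0], 1)]
        )
        got = get_hits(aln, Region(1, 1, 100), HitFilter(minweight=1.0))
        assert sorted(got.weight.tolist()) == [1.0, 2.0]

    def test_unknown_chromosome_is_empty_not_error(self, make_alignment):
        aln = make_alignment()
        aln.append_single(1, [SingleHit(1, 10, "+", 36)])
        assert len(get_hits(aln, Region(99, 1, 100))) == 0
        assert count_hits(aln, Region(99, 1, 100)) == 0
        assert sum_weights(aln, Region(99, 1, 100)) == 0.0

    def test_projections_match_full_result(self, make_alignment):
        ds = generate(GenSpec(seed=1, n_reads=300, n_chroms=1, weight_model="uniform"))
        aln = store_dataset(make_alignment(), ds)
        region = Region(1, 200_000, 800_000)
        full = get_hits(aln, region)
        assert get_hits(aln, region, projection="positions").tolist() == full.pos.tolist()
        assert get_hits(aln, region, projection="weights").tolist() == full.weight.tolist()

    def test_count_whole_store_is_conserved(self, make_alignment):
        ds = generate(GenSpec(seed=2, n_reads=1000))
        aln = store_dataset(make_alignment(), ds)
        assert count_hits(aln) == 1000

    def test_count_additive_over_partition_of_chromosome(self, make_alignment):
        ds = generate(GenSpec(seed=3, n_reads=800, n_chroms=1))
        aln = store_dataset(make_alignment(), ds)
        cuts = [1, 250_000, 500_000, 750_000, 10**6]
        total = sum(
            count_hits(aln, Region(1, lo, hi - 1))
            for lo, hi in zip(cuts[:-1], cuts[1:])
        ) + count_hits(aln, Region(1, 10**6, 10**6))
        assert total == count_hits(aln, chrom=1)

    def test_unit_weights_sum_equals_count(self, make_alignment):
        ds = generate(GenSpec(seed=4, n_reads=500, n_chroms=1))
        aln = store_dataset(make_alignment(), ds)
        r = Region(1, 1, 10**6)
        assert sum_weights(aln, r) == count_hits(aln, r)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(5))
    def test_randomized_queries_match_full_scan(self, make_alignment, seed):
        """Indexed get_hits/count/sum/histogram agree with the brute-force
        oracle over random datasets, regions, and filters."""
        spec = GenSpec(seed=seed, n_reads=2000, n_chroms=2,
                       paired_fraction=0.3, weight_model="multiplicity")
        ds = generate(spec)
        aln = store_dataset(make_alignment(f"a{seed}"), ds)
        rng = np.random.default_rng(1000 + seed)
        for _ in range(40):
            chrom = int(rng.integers(1, 3))
            s = int(rng.integers(1, spec.pos_max))
            e = min(int(s + rng.integers(1, spec.pos_max // 2)), spec.pos_max)
            region = Region(chrom, s, e)
            filt = HitFilter(
                strand=str(rng.choice(["+", "-", "both"])),
                minweight=float(rng.choice([0.0, 0.3, 1.0])) if rng.random() < 0.5 else None,
                endedness=str(rng.choice(["single", "pairedL", "pairedR"])),
            )
            assert count_hits(aln, region, filt=filt) == ds.oracle.count(region, filt=filt)
            assert sum_weights(aln, region, filt=filt) == pytest.approx(
                ds.oracle.weight_sum(region, filt=filt), rel=1e-6, abs=1e-9
            )
            got = get_hits(aln, region, filt, projection="positions")
            assert np.array_equal(np.sort(got), ds.oracle.positions(region, filt))
            bw = int(rng.choice([1, 37, 500, 10_000]))
            h = histogram(aln, region, bw, mode="count", filt=filt)
            assert h.bins == ds.oracle.histogram(region, bw, "count", filt).bins


class TestHistogram:
    def test_one_hit_per_bin_example(self, make_alignment):
        aln = make_alignment()
        aln.append_single(1, [SingleHit(1, p, "+", 36) for p in (5, 15, 25)])
        h = histogram(aln, Region(1, 1, 30), 10)
        assert h.bins == {1: 1, 11: 1, 21: 1}

    def test_degenerate_single_bin(self, make_alignment):
        ds = generate(GenSpec(seed=5, n_reads=200, n_chroms=1))
        aln = store_dataset(make_alignment(), ds)
        r = Region(1, 1, 10**6)
        h = histogram(aln, r, 10**6)
        assert h.bins == {1: count_hits(aln, r)}

    def test_bins_anchor_at_region_start(self, make_alignment):
        aln = make_alignment()
        aln.append_single(1, [SingleHit(1, 107, "+", 36)])
        h = histogram(aln, Region(1, 103, 200), 10)
        assert list(h.bins) == [103]

    def test_binwidth_must_be_positive(self, make_alignment):
        aln = make_alignment()
        with pytest.raises(ValueError):
            histogram(aln, Region(1, 1, 10), 0)

    def test_conservation_count_and_weight(self, make_alignment):
        """Sum of count bins == count_hits; sum of weight bins ==
        sum_weights (1e-6 relative), over random regions/binwidths."""
        ds = generate(GenSpec(seed=6, n_reads=2000, n_chroms=1, weight_model="multiplicity"))
        aln = store_dataset(make_alignment(), ds)
        rng = np.random.default_rng(7)
        for _ in range(25):
            s = int(rng.integers(1, 10**6))
            e = min(s + int(rng.integers(1, 400_000)), 10**6)
            bw = int(rng.integers(1, 50_000))
            r = Region(1, s, e)
            hc = histogram(aln, r, bw, mode="count")
            assert hc.total == count_hits(aln, r)
            hw = histogram(aln, r, bw, mode="weight")
            assert hw.total == pytest.approx(sum_weights(aln, r), rel=1e-6, abs=1e-12)


class TestIOBound:
    def test_records_decoded_bounded_by_m_plus_two_blocks(self, make_alignment):
        """The indexed scan decodes at most m + 2B records per region
        query — the measurable form of the O(log n + m) contract."""
        ds = generate(GenSpec(seed=8, n_reads=50_000, n_chroms=1))
        aln = store_dataset(make_alignment(), ds)
        rng = np.random.default_rng(9)
        for _ in range(30):
            s = int(rng.integers(1, 10**6))
            e = min(s + int(rng.integers(1, 100_000)), 10**6)
            stats = QueryStats()
            m = count_hits(aln, Region(1, s, e), stats=stats)
            assert stats.records_decoded <= m + 2 * BLOCK_RECORDS


class TestListChromosomes:
    def test_reflects_stored_and_deleted_chroms(self, make_alignment):
        aln = make_alignment()
        aln.append_single(1, [SingleHit(1, 10, "+", 36)])
        aln.append_single(5, [SingleHit(5, 10, "+", 36)])
        assert set(list_chromosomes(aln)) == {1, 5}
        aln.delete(chrom=5)
        assert set(list_chromosomes(aln)) == {1}

    def test_empty_alignment_lists_nothing(self, make_alignment):
        assert list_chromosomes(make_alignment()) == {}
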