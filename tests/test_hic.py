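"""Contact-map binning and interaction ranking (procedure Steps 1-3)."""

import numpy as np
import pytest

from remreg.core import CoordinateError, GenomicInterval
from remreg.hic import (ContactMap, bin_of, gene_bins, interaction_summary,
                        rank_interacting)

GENE = GenomicInterval.from_printed(2_645_885, 2_795_015, "chr18")


class TestBinOf:
    @pytest.mark.parametrize("pos,size,expected", [
        (2_645_885, 1_000_000, 2_000_000),  # gene start falls in the 2-Mb bin
        (2_795_015, 100_000, 2_700_000),    # gene end falls in fragment 2
        (1, 1_000_000, 0),
        (1, 7, 0),
    ])
    def test_examples(self, pos, size, expected):
        assert bin_of(pos, size) == expected

    def test_position_below_one_rejected(self):
        with pytest.raises(CoordinateError):
            bin_of(0, 100)

    def test_bin_brackets_position(self):
        rng = np.random.default_rng(3)
        for _ in range(2_000):
            pos = int(rng.integers(1, 10**8))
            size = int(rng.integers(1, 10**6))
            b = bin_of(pos, size)
            assert b <= pos - 1 < b + size
            assert b % size == 0


class TestGeneBins:
    def test_gene_occupies_two_100kb_fragments(self):
        assert gene_bins(GENE, 100_000) == [2_600_000, 2_700_000]

    def test_gene_occupies_one_1mb_fragment(self):
        assert gene_bins(GENE, 1_000_000) == [2_000_000]

    def test_gene_inside_one_bin(self):
        iv = GenomicInterval("chr1", 150, 900)
        assert gene_bins(iv, 1_000) == [0]


def _paper_1mb_map():
    cmap = ContactMap("chr18", 1_000_000)
    cmap.set_count(2_000_000, 2_000_000, 3371)
    cmap.set_count(2_000_000, 3_000_000, 663)
    cmap.set_count(2_000_000, 1_000_000, 25)
    cmap.set_count(2_000_000, 4_000_000, 12)
    return cmap


class TestRankInteracting:
    def test_self_interaction_tops_the_ranking(self):
        ranking = rank_interacting(_paper_1mb_map(), [2_000_000], min_count=0)
        assert ranking.ranked[0] == (2_000_000, 3371)
        assert ranking.ranked[1] == (3_000_000, 663)

    def test_exclude_self_reports_self_counts_separately(self):
        ranking = rank_interacting(_paper_1mb_map(), [2_000_000],
                                   include_self=False)
        assert ranking.ranked[0] == (3_000_000, 663)
        assert all(b != 2_000_000 for b, _ in ranking.ranked)
        assert ranking.self_counts == {2_000_000: 3371}

    def test_all_zero_map_ranks_nothing(self):
        cmap = ContactMap("chr18", 1_000_000)
        assert rank_interacting(cmap, [0], min_count=0).ranked == []

    def test_ties_broken_by_ascending_bin_start(self):
        cmap = ContactMap("c", 10)
        cmap.set_count(0, 30, 5)
        cmap.set_count(0, 10, 5)
        ranking = rank_interacting(cmap, [0], min_count=1)
        assert ranking.ranked == [(10, 5), (30, 5)]

    def test_misaligned_gene_bin_rejected(self):
        with pytest.raises(CoordinateError):
            rank_interacting(_paper_1mb_map(), [2_500_000])

    @pytest.mark.parametrize("seed", range(15))
    def test_totals_match_dense_matrix_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 51))
        size = 100
        dense = np.triu(rng.integers(0, 50, size=(n, n)))
        dense = dense + np.triu(dense, 1).T  # symmetric
        cmap = ContactMap("c", size)
        for i in range(n):
            for j in range(i, n):
                if dense[i, j]:
                    cmap.set_count(i * size, j * size, int(dense[i, j]))
        g = sorted(rng.choice(n, size=int(rng.integers(1, 3)), replace=False))
        min_count = int(rng.integers(0, 30))
        ranking = rank_interacting(cmap, [int(b) * size for b in g], min_count)
        oracle = dense[g, :].sum(axis=0)
        expected = sorted(((b * size, int(oracle[b])) for b in range(n)
                           if oracle[b] >= max(min_count, 1)),
                          key=lambda bc: (-bc[1], bc[0]))
        assert ranking.ranked == expected
        counts = [c for _, c in ranking.ranked]
        assert counts == sorted(counts, reverse=True)


class TestInteractionSummary:
    def test_fragment_self_counts_per_bin(self, locus):
        # per-bin mode: each gene fragment interacts most strongly with itself
        for gbin, self_count in ((2_600_000, 256), (2_700_000, 237)):
            df = interaction_summary(locus.contacts_fine, [gbin])
            totals = dict(zip(df.bin_start, df.total_count))
            assert totals[gbin] == self_count

    def test_weak_neighbour_and_background_ceiling(self, locus):
        df = interaction_summary(locus.contacts_fine, [2_600_000, 2_700_000])
        totals = dict(zip(df.bin_start, df.total_count))
        assert totals[2_500_000] == 23         # the weakly interacting bin
        others = {b: c for b, c in totals.items()
                  if b not in (2_600_000, 2_700_000)}
        assert max(others.values()) <= 30      # background ceiling

    def test_empty_map_yields_empty_table(self):
        df = interaction_summary(ContactMap("c", 10), [0])
        assert df.empty
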