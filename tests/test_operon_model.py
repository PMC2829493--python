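import math
from itertools import combinations

import numpy as np
import pytest

from cheops.genome_io import GeneRecord
from cheops.operon_model import (
    NEG_INF,
    ClusterConfig,
    aicc_score,
    best_partition_for_k,
    candidate_segments,
    cluster_operons,
    pooled_within_ss,
    read_operon_table,
    write_operon_table,
)


def genes_from_gaps(gaps, strand="+", length=1000, species="sp", replicon="chr"):
    """Lay genes left to right with the given intergenic gaps."""
    genes, pos = [], 500
    for i in range(len(gaps) + 1):
        genes.append(
            GeneRecord(f"g{i}", species, replicon, pos, pos + length - 1, strand, "Y")
        )
        if i < len(gaps):
            pos += length + gaps[i]
    return genes


def brute_force_min_w(centres, k):
    """Independent oracle: minimal W over all contiguous partitions."""
    n = len(centres)
    best = math.inf
    for splits in combinations(range(1, n), k - 1):
        edges = [0, *splits, n]
        w = 0.0
        for lo, hi in zip(edges, edges[1:]):
            block = centres[lo:hi]
            mean = sum(block) / len(block)
            w += sum((x - mean) ** 2 for x in block)
        best = min(best, w)
    return best


class TestSegments:
    @pytest.mark.parametrize(
        "strands,sizes",
        [("+++", [3]), ("++-+", [2, 1, 1]), ("+", [1]), ("+-+-", [1, 1, 1, 1])],
    )
    def test_strand_flips_start_new_segments(self, strands, sizes):
        genes = genes_from_gaps([100] * (len(strands) - 1))
        genes = [
            GeneRecord(g.gene_id, g.species_id, g.replicon_id, g.start, g.end, s, g.che_type)
            for g, s in zip(genes, strands)
        ]
        segments = candidate_segments(genes)
        assert [len(s) for s in segments] == sizes
        assert [g for s in segments for g in s] == genes

    def test_empty_input(self):
        assert candidate_segments([]) == []


class TestFitStatistics:
    def test_pooled_within_ss_by_hand(self):
        assert pooled_within_ss([0, 10], [[0, 1]]) == 50
        assert pooled_within_ss([0, 10, 100, 110], [[0, 1], [2, 3]]) == 100
        assert pooled_within_ss([5, 7, 9], [[0], [1], [2]]) == 0

    def test_empty_block_is_an_error(self):
        with pytest.raises(ValueError, match="empty block"):
            pooled_within_ss([1, 2], [[0, 1], []])

    def test_aicc_values(self):
        assert aicc_score(1.0, 5, 2) == pytest.approx(5.0)
        assert aicc_score(math.e, 4, 1) == pytest.approx(4.0)

    def test_aicc_zero_w_sentinel_compares_below_everything(self):
        assert aicc_score(0.0, 7, 3) == NEG_INF
        assert aicc_score(0.0, 7, 3) < aicc_score(1e-300, 7, 3)

    @pytest.mark.parametrize("n,k", [(3, 4), (1, 2)])
    def test_aicc_rejects_k_above_n(self, n, k):
        with pytest.raises(ValueError):
            aicc_score(1.0, n, k)


class TestBestPartition:
    def test_unique_optimum(self):
        fit = best_partition_for_k([0, 1, 1000, 1001], 2)
        assert fit.assignment == (0, 0, 1, 1)
        assert fit.w_k == pytest.approx(1.0)

    def test_k_equals_one_is_single_block(self):
        fit = best_partition_for_k([3, 7, 100], 1)
        assert fit.assignment == (0, 0, 0)

    def test_matches_exhaustive_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            n = int(rng.integers(2, 13))
            centres = sorted(rng.uniform(0, 1e5, size=n))
            k = int(rng.integers(1, n + 1))
            fit = best_partition_for_k(centres, k)
            assert fit.w_k == pytest.approx(
                brute_force_min_w(centres, k), rel=1e-9, abs=1e-9
            )

    def test_atomic_blocks_are_never_split(self):
        fit = best_partition_for_k(
            [0, 1, 2, 3], 2, atomic_blocks=[[0, 1], [2, 3]]
        )
        assert fit.assignment == (0, 0, 1, 1)

    def test_forbidden_join_forces_the_split(self):
        # W favours splitting between 1 and 2, but the join ban at boundary 1
        # forces a split between genes 0 and 1
        fit = best_partition_for_k([0, 1, 1000, 1001], 2, forbidden_joins=[1])
        assert fit.assignment == (0, 1, 1, 1)

    def test_infeasible_k_is_an_error(self):
        with pytest.raises(ValueError):
            best_partition_for_k([0, 1], 2, atomic_blocks=[[0, 1]])

    def test_refinement_never_increases_w(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            n = int(rng.integers(3, 12))
            centres = sorted(rng.uniform(0, 1e5, size=n))
            for k in range(1, n):
                w_k = best_partition_for_k(centres, k).w_k
                w_k1 = best_partition_for_k(centres, k + 1).w_k
                assert w_k1 <= w_k + 1e-9


class TestClusterOperons:
    def test_genes_within_merge_distance_share_an_operon(self):
        operons = cluster_operons(genes_from_gaps([2000]))
        assert len(operons) == 1 and len(operons[0].genes) == 2

    def test_genes_beyond_split_distance_are_separated(self):
        operons = cluster_operons(genes_from_gaps([150_000]))
        assert [len(op.genes) for op in operons] == [1, 1]

    def test_aicc_splits_the_wide_middle_gap(self):
        # gaps 500 | 60,000 | 500: neither hard constraint decides the middle
        operons = cluster_operons(genes_from_gaps([500, 60_000, 500]))
        assert [len(op.genes) for op in operons] == [2, 2]

    def test_union_of_operons_is_the_input(self):
        genes = genes_from_gaps([500, 60_000, 150_000, 500, 2_000])
        operons = cluster_operons(genes)
        clustered = [g for op in operons for g in op.genes]
        assert sorted(clustered, key=lambda g: g.start) == genes

    def test_plasmid_and_chromosome_never_co_cluster(self):
        genes = genes_from_gaps([500]) + [
            GeneRecord("p1", "sp", "plasmid", 500, 1500, "+", "A")
        ]
        operons = cluster_operons(genes)
        assert {op.replicon_id for op in operons} == {"chr", "plasmid"}
        assert all(
            len({g.replicon_id for g in op.genes}) == 1 for op in operons
        )

    def test_within_gaps_smaller_than_between_gaps(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            gaps = [int(rng.choice([200, 1500, 40_000, 70_000, 200_000]))
                    for _ in range(int(rng.integers(1, 9)))]
            genes = genes_from_gaps(gaps)
            operons = cluster_operons(genes)
            borders = {}
            for op in operons:
                for g in op.genes:
                    borders[g.gene_id] = op.operon_id
            within, between = [], []
            for a, b in zip(genes, genes[1:]):
                gap = b.start - a.end
                (within if borders[a.gene_id] == borders[b.gene_id] else between).append(gap)
            if within and between:
                assert max(within) < min(between)

    def test_mixed_species_input_rejected(self):
        genes = genes_from_gaps([500]) + genes_from_gaps([500], species="sp2")
        with pytest.raises(ValueError, match="one species"):
            cluster_operons(genes)

    def test_operon_table_round_trip(self, tmp_path):
        operons = cluster_operons(genes_from_gaps([500, 150_000, 2_000]))
        path = tmp_path / "operons.tsv"
        write_operon_table(operons, path)
        assert read_operon_table(path) == operons

    def test_centre_distance_mode(self):
        config = ClusterConfig(distance_mode="centre")
        # centre distance = gap + gene length (1000); 2,400 bp gap merges
        operons = cluster_operons(genes_from_gaps([2_400]), config)
        assert len(operons) == 1

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            ClusterConfig(merge_distance=200_000, split_distance=100_000)
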