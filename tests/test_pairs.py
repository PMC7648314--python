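"""Distance filtering, quantile binning, negative subsampling, domain assembly."""

import numpy as np
import pytest

from epidann.genomic import GenomicRegion
from epidann.pairs import (
    ConfigurationError,
    DomainDataset,
    EPIPair,
    SamplingError,
    assign_quantile_bins,
    build_domains,
    count_epi_overlap,
    dedupe_pairs,
    filter_by_distance,
    split_pairs,
    subsample_negatives,
)


def make_pair(distance, chrom="chr1", label=1, enh_start=1_000_000):
    """A pair whose center-to-center distance is exactly ``distance``."""
    enh = GenomicRegion(chrom, enh_start, enh_start + 400)
    pc = enh.center + distance
    prom = GenomicRegion(chrom, pc - 500, pc + 500)
    return EPIPair(enhancer=enh, promoter=prom, epi_label=label)


class TestDistanceFilter:
    @pytest.mark.parametrize(
        "distance,kept",
        [
            (10_000, False),  # strict lower bound
            (10_001, True),
            (1_000_000, True),
            (1_999_999, True),
            (2_000_000, False),  # strict upper bound
        ],
    )
    def test_strict_bounds(self, distance, kept):
        pairs = [make_pair(distance)]
        assert (len(filter_by_distance(pairs)) == 1) is kept

    def test_cross_chromosome_removed(self):
        enh = GenomicRegion("chr1", 0, 400)
        prom = GenomicRegion("chr2", 50_000, 51_000)
        assert filter_by_distance([EPIPair(enh, prom)]) == []
        assert EPIPair(enh, prom).distance is None


class TestQuantileBins:
    def test_even_distances_give_two_per_bin(self):
        # brute-force expectation: 10 equally frequent distances over 5
        # quantile bins -> exactly 2 positives per bin
        distances = [20, 30, 40, 50, 60, 70, 80, 90, 100, 110]
        pairs = [make_pair(d * 1000) for d in distances]
        binned, edges = assign_quantile_bins(pairs, n_bins=5)
        counts = np.bincount([p.bin_id for p in binned], minlength=5)
        assert counts.tolist() == [2, 2, 2, 2, 2]
        assert len(edges) == 4

    def test_degenerate_distribution_collapses_to_one_bin(self):
        pairs = [make_pair(50_000) for _ in range(8)]
        binned, _ = assign_quantile_bins(pairs, n_bins=5)
        assert {p.bin_id for p in binned} == {0}

    def test_single_bin_is_identity(self):
        pairs = [make_pair(d) for d in (20_000, 90_000, 400_000)]
        binned, edges = assign_quantile_bins(pairs, n_bins=1)
        assert {p.bin_id for p in binned} == {0}
        assert len(edges) == 0

    def test_fewer_positives_than_bins_rejected(self):
        with pytest.raises(ConfigurationError):
            assign_quantile_bins([make_pair(20_000)], n_bins=5)

    def test_edge_ties_go_to_lower_bin(self):
        # median of [10, 20, 20, 30] kb is exactly 20 kb, so the 20 kb pairs
        # sit on the bin edge and must fall into the lower bin
        distances = [10, 20, 20, 30]
        pairs = [make_pair(d * 1000) for d in distances]
        binned, edges = assign_quantile_bins(pairs, n_bins=2)
        assert edges[0] == 20_000
        at_edge = [p for p in binned if p.distance == edges[0]]
        assert len(at_edge) == 2 and all(p.bin_id == 0 for p in at_edge)


class TestNegativeSubsampling:
    def _setup(self, pos_distances, cand_distances, n_bins=2):
        positives = [make_pair(d) for d in pos_distances]
        binned, edges = assign_quantile_bins(positives, n_bins=n_bins)
        candidates = [make_pair(d, label=None, enh_start=2_000_000 + 1000 * i) for i, d in enumerate(cand_distances)]
        return binned, candidates, edges

    def test_per_bin_counts_match_positives(self):
        binned, candidates, edges = self._setup(
            [20_000, 25_000, 200_000], [21_000, 22_000, 23_000, 150_000, 160_000]
        )
        negs = subsample_negatives(binned, candidates, edges, seed=3)
        pos_counts = np.bincount([p.bin_id for p in binned], minlength=len(edges) + 1)
        neg_counts = np.bincount([p.bin_id for p in negs], minlength=len(edges) + 1)
        assert np.array_equal(pos_counts, neg_counts)
        assert all(p.epi_label == 0 for p in negs)

    def test_empty_bin_draws_nothing(self):
        # all positives share one distance -> they collapse into bin 0 and
        # the upper bin stays empty, so no negatives may come from it
        binned, candidates, edges = self._setup(
            [50_000, 50_000, 50_000], [48_000, 49_000, 49_500, 51_000, 52_000]
        )
        negs = subsample_negatives(binned, candidates, edges, seed=0)
        assert len(negs) == 3
        assert all(p.bin_id == 0 for p in negs)

    def test_deterministic_given_seed(self):
        binned, candidates, edges = self._setup(
            [20_000, 25_000, 200_000], [21_000, 22_000, 23_000, 150_000, 160_000, 170_000]
        )
        a = subsample_negatives(binned, candidates, edges, seed=11)
        b = subsample_negatives(binned, candidates, edges, seed=11)
        assert [p.coords() for p in a] == [p.coords() for p in b]
        c = subsample_negatives(binned, candidates, edges, seed=12)
        assert [p.coords() for p in a] != [p.coords() for p in c]

    def test_deficient_bin_reported(self):
        binned, candidates, edges = self._setup([20_000, 21_000, 300_000], [22_000])
        with pytest.raises(SamplingError, match="bin"):
            subsample_negatives(binned, candidates, edges, seed=0)


class TestOverlapCounting:
    def test_identical_sets_overlap_fully(self):
        a = [make_pair(50_000)]
        assert count_epi_overlap(a, list(a)) == 1

    def test_one_nt_shift_breaks_overlap(self):
        a = [make_pair(50_000)]
        shifted = EPIPair(
            enhancer=GenomicRegion("chr1", a[0].enhancer.start + 1, a[0].enhancer.end + 1),
            promoter=a[0].promoter,
            epi_label=1,
        )
        assert count_epi_overlap(a, [shifted]) == 0

    def test_empty_set(self):
        assert count_epi_overlap([make_pair(50_000)], []) == 0

    def test_symmetric_for_duplicate_free_sets(self):
        a = [make_pair(50_000), make_pair(60_000, enh_start=2_000_000)]
        b = [make_pair(60_000, enh_start=2_000_000), make_pair(70_000, enh_start=3_000_000)]
        assert count_epi_overlap(a, b) == count_epi_overlap(b, a) == 1


class TestDomainAssembly:
    def _tables(self, n_cells=3, n=20, enh_len=30, prom_len=20, seed=0):
        rng = np.random.default_rng(seed)
        tables = {}
        for i in range(n_cells):
            enh = rng.random((n, enh_len, 4)).astype(np.float32)
            prom = rng.random((n, prom_len, 4)).astype(np.float32)
            labels = (rng.random(n) < 0.5).astype(np.int8)
            tables[f"cell{i}"] = (enh, prom, labels)
        return tables

    def test_source_pools_non_target_cells(self):
        tables = self._tables(n_cells=4, n=10)
        source, t_train, t_test = build_domains(tables, "cell2", split_seed=0)
        assert source.n == 30
        assert set(source.cell_lines) == {"cell0", "cell1", "cell3"}
        assert source.domain_label == 0
        assert t_train.domain_label == t_test.domain_label == 1

    @pytest.mark.parametrize("n", [20, 21])
    def test_half_split_and_label_stripping(self, n):
        tables = self._tables(n=n)
        _, t_train, t_test = build_domains(tables, "cell0", split_seed=1)
        assert t_train.n == n // 2
        assert t_test.n == n - n // 2
        assert t_train.epi_label is None
        assert t_test.epi_label is not None

    def test_split_is_disjoint_and_seed_dependent(self):
        tables = self._tables(n=16)
        _, tr1, te1 = build_domains(tables, "cell0", split_seed=5)
        _, tr2, _ = build_domains(tables, "cell0", split_seed=6)
        # disjointness: every target sample lands in exactly one split
        joined = np.concatenate([tr1.enh, te1.enh])
        original = tables["cell0"][0]
        assert np.array_equal(np.sort(joined, axis=None), np.sort(original, axis=None))
        assert not np.array_equal(tr1.enh, tr2.enh)

    def test_missing_target_cell_rejected(self):
        with pytest.raises(ConfigurationError):
            build_domains(self._tables(), "nope", split_seed=0)

    def test_single_cell_line_rejected(self):
        with pytest.raises(ConfigurationError):
            build_domains(self._tables(n_cells=1), "cell0", split_seed=0)


class TestPairHygiene:
    def test_dedupe_keeps_first(self):
        a = make_pair(50_000)
        dup = EPIPair(a.enhancer, a.promoter, epi_label=1)
        assert dedupe_pairs([a, dup, make_pair(60_000)]) == [a, make_pair(60_000)]

    def test_split_pairs_disjoint(self):
        pairs = [make_pair(20_000 + i * 1000, enh_start=i * 10_000) for i in range(9)]
        tr, te = split_pairs(pairs, seed=2)
        assert len(tr) == 4 and len(te) == 5
        assert not {p.coords() for p in tr} & {p.coords() for p in te}
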