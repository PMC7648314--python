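"""Kernel-to-motif extraction, PFMs, MEME export and relative importance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epidann.genomic import one_hot_encode
from epidann.motifs import (
    PFM,
    best_subsequence,
    build_pfm,
    compare_models,
    consensus_identity,
    extract_kernel_pfms,
    relative_importance,
    write_meme,
)


def scan_activations(sequence, kernels):
    """Brute-force dot-product scan of one-hot kernels over a sequence."""
    onehot = one_hot_encode(sequence)
    K = kernels.shape[1]
    L = len(sequence) - K + 1
    acts = np.zeros((L, kernels.shape[0]))
    for k, kernel in enumerate(kernels):
        for i in range(L):
            acts[i, k] = float((onehot[i : i + K] * kernel).sum())
    return acts


class TestBestSubsequence:
    def test_matching_kernel_recovers_planted_substring(self):
        seq = "A" * 20 + "ACGTACGT" + "A" * 20
        kernel = one_hot_encode("ACGTACGT")[None]  # exact one-hot pattern
        acts = scan_activations(seq, kernel)
        assert best_subsequence(0, seq, acts, 8) == "ACGTACGT"

    def test_nonpositive_activation_skipped(self):
        acts = np.zeros((10, 1))
        assert best_subsequence(0, "A" * 19, acts, 10) is None

    def test_tie_resolves_leftmost(self):
        seq = "CCGGCCGG" + "TT"
        kernel = one_hot_encode("CCGG")[None]
        acts = scan_activations(seq, kernel)
        assert int(np.argmax(acts[:, 0])) == 0
        assert best_subsequence(0, seq, acts, 4) == "CCGG"

    def test_kernel_out_of_range(self):
        with pytest.raises(IndexError):
            best_subsequence(3, "ACGT", np.zeros((1, 2)), 2)


class TestPFM:
    def test_counting(self):
        pfm = build_pfm(["AC", "AC", "AT"])
        assert pfm.counts[0].tolist() == [3, 0, 0, 0]
        assert pfm.counts[1].tolist() == [0, 2, 0, 1]

    def test_single_sequence_is_indicator(self):
        pfm = build_pfm(["ACGT"])
        assert np.array_equal(pfm.counts, np.eye(4, dtype=int))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            build_pfm([])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            build_pfm(["ACGT", "ACG"])

    @given(st.lists(st.text(alphabet="ACGT", min_size=6, max_size=6), min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_column_sums_equal_n_sequences(self, seqs):
        pfm = build_pfm(seqs)
        assert np.all(pfm.counts.sum(axis=1) == len(seqs))

    def test_consensus_argmax(self):
        assert build_pfm(["AC", "AC", "GC"]).consensus == "AC"


class TestMemeExport:
    def test_probability_rows_sum_to_one(self, tmp_path):
        pfm = build_pfm(["AC", "AG", "AT", "AA"], kernel_id=3, branch="enhancer")
        path = tmp_path / "motifs.meme"
        assert write_meme([pfm], path) == 1
        text = path.read_text()
        assert text.startswith("MEME version 4")
        assert "ALPHABET= ACGT" in text
        assert "MOTIF enhancer_kernel_3" in text
        assert "nsites= 4" in text
        rows = [
            [float(v) for v in line.split()]
            for line in text.splitlines()
            if line.startswith(" ")
        ]
        assert len(rows) == 2
        for row in rows:
            assert sum(row) == pytest.approx(1.0)

    def test_default_background_uniform(self, tmp_path):
        path = tmp_path / "m.meme"
        write_meme([build_pfm(["AC"])], path)
        assert "A 0.25000 C 0.25000 G 0.25000 T 0.25000" in path.read_text()

    def test_zero_count_pfm_skipped_with_warning(self, tmp_path):
        empty = PFM(kernel_id=0, counts=np.zeros((4, 4), dtype=int), n_sequences=0)
        with pytest.warns(UserWarning):
            n = write_meme([empty], tmp_path / "m.meme")
        assert n == 0

    def test_bad_background_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            write_meme([build_pfm(["AC"])], tmp_path / "m.meme", background=(0.5, 0.5, 0.5, 0.5))


class TestRelativeImportance:
    @pytest.mark.parametrize(
        "n_w,n_wo,rank,expected",
        [(10, 0, 1, 1.0), (5, 5, 3, 0.0), (10, 5, 2, 0.25)],
    )
    def test_enumerated_cases(self, n_w, n_wo, rank, expected):
        assert relative_importance(n_w, n_wo, rank) == pytest.approx(expected)

    def test_zero_occurrences_rejected(self):
        with pytest.raises(ValueError):
            relative_importance(0, 3, 1)

    @given(
        st.integers(1, 50), st.integers(0, 50), st.integers(0, 50), st.integers(1, 10)
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_n_without_and_rank_and_bounded(self, n_w, n_wo, delta, rank):
        base = relative_importance(n_w, n_wo, rank)
        assert base <= 1.0 / rank + 1e-12
        assert relative_importance(n_w, n_wo + delta, rank) <= base
        assert abs(relative_importance(n_w, n_wo, rank + 1)) <= abs(base) or base == 0


class TestCompareModels:
    def test_motif_only_in_transfer_model_scores_inverse_rank(self):
        ranked = compare_models([["m1", "m1", "m2"]], [["m2"]])
        by_id = {r.motif_id: r for r in ranked}
        assert by_id["m1"].score == pytest.approx(1.0)  # N_wo=0, rank 1
        assert by_id["m2"].n_without == 1

    def test_identical_models_score_zero(self):
        ranked = compare_models([["a", "b"]], [["a", "b"]])
        assert all(r.score == 0.0 for r in ranked)

    def test_counts_aggregate_across_repeats(self):
        ranked = compare_models([["a"], ["a"], ["b"]], [[]])
        by_id = {r.motif_id: r for r in ranked}
        assert by_id["a"].n_with == 2 and by_id["a"].rank_with == 1
        assert by_id["b"].n_with == 1 and by_id["b"].rank_with == 2

    def test_rank_ties_share_minimum(self):
        ranked = compare_models([["a", "b"]], [[]])
        assert all(r.rank_with == 1 for r in ranked)
        assert all(r.score == pytest.approx(1.0) for r in ranked)

    def test_empty_sets_empty_report(self):
        assert compare_models([], []) == []


class TestConsensusIdentity:
    def test_exact_substring_full_identity(self):
        assert consensus_identity("AAACGTACGTAA", "ACGTACGT") == 1.0

    def test_partial_identity(self):
        # best alignment of ACGG inside TTACGTTT matches 3/4
        assert consensus_identity("TTACGTTT", "ACGG") == pytest.approx(0.75)


class TestKernelExtraction:
    def test_planted_kernel_pfm_matches_plant(self):
        """A network whose first-layer kernel IS the motif pattern yields a
        PFM whose consensus equals the motif."""
        from epidann.model import ModelConfig, Network

        cfg = ModelConfig(
            variant="source_only", enh_len=60, prom_len=40, n_kernels=2, kernel_len=6,
            pool_len=5, pool_stride=5, n_conv_layers=1, lstm_dim=4, epi_dense_dim=4,
            domain_dense_dim=4,
        )
        net = Network(cfg, seed=0)
        motif = "TGACGT"
        net.enh_convs[0].w.data[:] = 0
        net.enh_convs[0].w.data[:, :, 0] = one_hot_encode(motif)
        net.enh_convs[0].b.data[:] = 0
        rng = np.random.default_rng(0)
        seqs = []
        for _ in range(20):
            s = "".join(rng.choice(list("ACGT"), size=60))
            pos = int(rng.integers(0, 60 - 6))
            seqs.append(s[:pos] + motif + s[pos + 6 :])
        pfms = extract_kernel_pfms(net, seqs, branch="enhancer")
        kernel0 = next(p for p in pfms if p.kernel_id == 0)
        assert kernel0.consensus == motif
        assert np.all(kernel0.counts.sum(axis=1) == kernel0.n_sequences)
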