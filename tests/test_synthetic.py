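"""The planted-motif generator, its manifests, and the genome fixture."""

import dataclasses
import json

import numpy as np
import pytest

from epidann.genomic import read_pairs, read_regions
from epidann.pairs import EPIPair, dedupe_pairs, filter_by_distance
from epidann.synthetic import (
    SynthConfig,
    benchmark_domains,
    decode_dataset,
    domain_shift_probe,
    generate_domain,
    generate_genome_fixture,
    null_benchmark_config,
    scan_labels,
    shifted_benchmark_config,
)


@pytest.fixture(scope="module")
def small_cfg():
    return SynthConfig(n_pairs_per_domain=100, enh_len=150, prom_len=100, seed=3)


class TestGenerateDomain:
    def test_exact_label_balance(self, small_cfg):
        ds = generate_domain(small_cfg, 0)
        assert int(ds.epi_label.sum()) == 50

    def test_positives_carry_both_motifs_negatives_at_most_one(self, small_cfg):
        ds = generate_domain(small_cfg, 0)
        for (enh, prom), label in zip(decode_dataset(ds), ds.epi_label):
            has_e = small_cfg.enh_motif in enh
            has_p = small_cfg.prom_motif in prom
            if label == 1:
                assert has_e and has_p
            else:
                assert not (has_e and has_p)

    def test_scan_recovers_labels_exactly(self, small_cfg):
        # with insertion prob 1 and no mutation, motif co-occurrence IS the label
        ds = generate_domain(small_cfg, 0)
        assert np.array_equal(scan_labels(ds, small_cfg), ds.epi_label)

    def test_deterministic_given_config(self, small_cfg):
        a = generate_domain(small_cfg, 1)
        b = generate_domain(SynthConfig(**{f.name: getattr(small_cfg, f.name) for f in dataclasses.fields(small_cfg)}), 1)
        assert np.array_equal(a.enh, b.enh)
        assert np.array_equal(a.epi_label, b.epi_label)
        assert a.manifest == b.manifest

    def test_domains_differ_only_by_domain_id_stream(self, small_cfg):
        a = generate_domain(small_cfg, 0)
        b = generate_domain(small_cfg, 1)
        assert not np.array_equal(a.enh, b.enh)

    def test_one_hot_rows_sum_to_one(self, small_cfg):
        ds = generate_domain(small_cfg, 0)
        assert np.array_equal(ds.enh.sum(axis=2), np.ones(ds.enh.shape[:2], dtype=np.float32))

    def test_motif_longer_than_sequence_rejected(self):
        with pytest.raises(ValueError):
            SynthConfig(enh_len=8, enh_motif="ACGTACGTACGT")

    def test_decoy_equal_to_motif_rejected(self):
        with pytest.raises(ValueError, match="decoy"):
            SynthConfig(decoy_motifs=(("TGACGTCATC",), ()))

    def test_gc_content_tracks_configuration(self):
        cfg = SynthConfig(
            n_pairs_per_domain=60, enh_len=300, prom_len=200,
            background_gc=(0.3, 0.7), seed=1,
        )
        gc = []
        for domain_id in (0, 1):
            ds = generate_domain(cfg, domain_id)
            gc.append(float(ds.enh[:, :, 1:3].sum() / ds.enh.sum()))
        assert gc[0] == pytest.approx(0.3, abs=0.03)
        assert gc[1] == pytest.approx(0.7, abs=0.03)


class TestBenchmarkConfigs:
    def test_shifted_config_has_gc_shift_and_target_decoys(self):
        cfg = shifted_benchmark_config(seed=0)
        assert cfg.background_gc == (0.40, 0.60)
        assert cfg.decoy_motifs[0] == ()
        assert len(cfg.decoy_motifs[1]) == 2
        for decoy, motif in zip(cfg.decoy_motifs[1], (cfg.enh_motif, cfg.prom_motif)):
            mismatches = sum(a != b for a, b in zip(decoy, motif))
            assert mismatches == 1

    def test_null_config_domains_identical_in_distribution(self):
        cfg = null_benchmark_config(seed=0)
        assert cfg.background_gc[0] == cfg.background_gc[1]
        assert cfg.decoy_motifs == ((), ())

    def test_benchmark_domains_split(self):
        cfg = SynthConfig(n_pairs_per_domain=50, enh_len=120, prom_len=80, seed=2)
        source, target_train, target_test = benchmark_domains(cfg)
        assert source.n == 50
        assert target_train.n == 25 and target_test.n == 25
        assert target_train.epi_label is None
        assert target_test.epi_label is not None


class TestShiftProbe:
    def test_no_shift_probe_near_chance_and_symmetric(self):
        cfg = SynthConfig(n_pairs_per_domain=150, enh_len=200, prom_len=120, seed=5)
        a = generate_domain(cfg, 0)
        b = generate_domain(cfg, 1)
        acc_ab = domain_shift_probe(a, b, seed=0)
        acc_ba = domain_shift_probe(b, a, seed=0)
        assert abs(acc_ab - 0.5) < 0.12
        assert acc_ab == pytest.approx(acc_ba, abs=1e-12)

    def test_gc_shift_is_detectable(self):
        cfg = SynthConfig(
            n_pairs_per_domain=150, enh_len=200, prom_len=120,
            background_gc=(0.40, 0.60), seed=5,
        )
        acc = domain_shift_probe(generate_domain(cfg, 0), generate_domain(cfg, 1), seed=0)
        assert acc > 0.8


@pytest.fixture(scope="module")
def fixture(tmp_path_factory):
    return generate_genome_fixture(seed=4, out_dir=tmp_path_factory.mktemp("fix"))


class TestGenomeFixture:
    def test_manifest_count_matches_distance_filter(self, fixture):
        raw = read_pairs(fixture.pairs_tsv)
        pairs = [EPIPair(e, p, lab) for e, p, lab in raw]
        kept = filter_by_distance(pairs)
        assert len(kept) == fixture.manifest["n_surviving_distance_filter"]
        assert len(dedupe_pairs(kept)) == fixture.manifest["n_surviving_unique"]

    def test_straddles_both_bounds(self, fixture):
        raw = read_pairs(fixture.pairs_tsv)
        distances = [EPIPair(e, p, lab).distance for e, p, lab in raw]
        assert 10_000 in distances  # at the strict lower bound -> removed
        assert 2_000_000 in distances  # at the strict upper bound -> removed
        assert None in distances  # cross-chromosome record

    def test_contains_planted_duplicate(self, fixture):
        raw = read_pairs(fixture.pairs_tsv)
        pairs = [EPIPair(e, p, lab) for e, p, lab in raw]
        assert len(dedupe_pairs(pairs)) < len(pairs)

    def test_elements_near_chromosome_ends_exercise_padding(self, fixture):
        from epidann.genomic import extract_window, load_genome

        genome = load_genome(fixture.genome_path)
        enhancers = read_regions(fixture.enhancer_bed, kind="enhancer")
        windows = [extract_window(r, 3000, genome) for r in enhancers]
        assert any("N" in w.seq for w in windows)
        assert all(len(w) == 3000 for w in windows)

    def test_manifest_json_parses(self, fixture):
        manifest = json.loads(fixture.manifest_path.read_text())
        assert manifest == fixture.manifest
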