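"""Synthetic benchmark data with planted motif-pair signal and domain shift.

The generator emulates the statistical structure the method assumes, at desk
scale:

* every sample is an (enhancer, promoter) sequence pair; *positives* carry a
  planted enhancer motif AND a planted promoter motif at uniform random
  positions, *negatives* carry exactly one of the two (chosen at random), so
  the label is a function of motif co-occurrence, not of either motif alone;
* background bases are i.i.d. with a domain-specific GC content — the
  covariate shift the domain discriminator can exploit and the reversal
  layer must neutralize;
* optional per-domain decoy motifs are inserted in both classes, adding a
  shift that is sequence-patterned rather than compositional;
* an optional per-position mutation rate degrades planted motifs, emulating
  the degeneracy of real transcription-factor binding sites.

A second generator emits a small on-disk fixture (FASTA genome + BED elements
+ labeled pair TSV + JSON manifest) whose pair distances straddle the 10 kb
and 2 Mb filter bounds, for end-to-end tests of the file-based pipeline.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .pairs import DomainDataset

_BASES = np.array(list("ACGT"))
_CODE = {b: i for i, b in enumerate("ACGT")}


@dataclass
class SynthConfig:
    n_pairs_per_domain: int = 2000
    enh_len: int = 500
    prom_len: int = 300
    enh_motif: str = "TGACGTCATC"
    prom_motif: str = "CCGGAAGTGA"
    motif_insertion_prob_positive: float = 1.0
    # probability that a negative carries one (never both) of the motifs;
    # real non-interacting pairs contain binding motifs at background rates,
    # so negatives are not uniformly motif-free
    motif_insertion_prob_negative: float = 0.5
    motif_mut_rate: float = 0.0
    # copies of a planted motif per carrying sequence; regulatory elements
    # typically contain several occurrences of a functional binding site, and
    # the repeated signal is what makes the desk-scale task learnable within
    # a short SGD budget
    n_motif_copies: int = 3
    background_gc: tuple[float, float] = (0.5, 0.5)  # (source, target)
    decoy_motifs: tuple[tuple[str, ...], tuple[str, ...]] = ((), ())
    decoy_insertion_prob: float = 1.0
    label_balance: float = 0.5
    seed: int = 0

    def __post_init__(self):
        for m in (self.enh_motif, self.prom_motif):
            if set(m) - set("ACGT"):
                raise ValueError(f"motif {m!r} must be over ACGT")
        if len(self.enh_motif) > self.enh_len or len(self.prom_motif) > self.prom_len:
            raise ValueError("motif longer than sequence")
        for gc in self.background_gc:
            if not 0 < gc < 1:
                raise ValueError("background_gc must be in (0, 1)")
        for domain_decoys in self.decoy_motifs:
            for d in domain_decoys:
                if d in (self.enh_motif, self.prom_motif):
                    raise ValueError(f"decoy {d!r} equals a label-defining motif")

    def manifest(self, domain_id: int) -> dict:
        d = asdict(self)
        d["decoy_motifs"] = [list(x) for x in self.decoy_motifs]
        d["background_gc"] = list(self.background_gc)
        d["domain_id"] = domain_id
        return d


def shifted_benchmark_config(seed: int = 0, n_pairs: int = 2000) -> SynthConfig:
    """The standard desk-scale transfer benchmark.

    Source and target share the label-defining motif pair but differ in
    background composition (GC 0.40 vs 0.60) and in a target-only decoy for
    each motif (one substitution away from the true consensus, planted at the
    same copy number).  A source-trained detector that cannot tell decoy from
    motif mis-scores target negatives; domain-invariant features require
    sharp detectors, which is what the adversary rewards.
    """
    cfg = SynthConfig(n_pairs_per_domain=n_pairs, seed=seed, background_gc=(0.40, 0.60))
    return dataclasses.replace(
        cfg,
        decoy_motifs=((), (_one_mismatch(cfg.enh_motif), _one_mismatch(cfg.prom_motif))),
    )


def null_benchmark_config(seed: int = 0, n_pairs: int = 2000) -> SynthConfig:
    """Identical source/target generators (no shift): the sanity null."""
    return SynthConfig(n_pairs_per_domain=n_pairs, seed=seed, background_gc=(0.5, 0.5))


def _one_mismatch(motif: str, position: Optional[int] = None) -> str:
    """Deterministic single-substitution decoy (middle base cycled A->C->G->T->A)."""
    position = len(motif) // 2 if position is None else position
    bases = "ACGT"
    repl = bases[(bases.index(motif[position]) + 1) % 4]
    return motif[:position] + repl + motif[position + 1 :]


@dataclass
class SynthDataset:
    """Generated one-hot samples plus ground-truth metadata."""

    enh: np.ndarray  # (n, enh_len, 4) float32
    prom: np.ndarray
    epi_label: np.ndarray  # (n,) int8
    domain_label: int
    enh_motif_pos: np.ndarray  # planted position or -1
    prom_motif_pos: np.ndarray
    manifest: dict

    @property
    def n(self) -> int:
        return self.enh.shape[0]

    def to_domain_dataset(self, role: str, labeled: Optional[bool] = None) -> DomainDataset:
        if labeled is None:
            labeled = role != "target_train"
        return DomainDataset(
            enh=self.enh,
            prom=self.prom,
            epi_label=self.epi_label if labeled else None,
            domain_label=self.domain_label,
            role=role,
            cell_lines=(f"synthetic-domain-{self.domain_label}",),
        )


def _insert(codes: np.ndarray, motif_codes: np.ndarray, pos: int, rng, mut_rate: float):
    m = motif_codes.copy()
    if mut_rate > 0:
        hits = rng.random(m.size) < mut_rate
        if hits.any():
            # mutate to a uniformly chosen *different* base
            shift = rng.integers(1, 4, size=int(hits.sum()))
            m[hits] = (m[hits] + shift) % 4
    codes[pos : pos + m.size] = m


def _plant(codes: np.ndarray, motif_codes: np.ndarray, L: int, rng, mut_rate: float, copies: int) -> int:
    """Insert ``copies`` occurrences at uniform positions; returns the last
    (guaranteed-intact under zero mutation) insertion position."""
    pos = -1
    for _ in range(copies):
        pos = int(rng.integers(0, L - motif_codes.size + 1))
        _insert(codes, motif_codes, pos, rng, mut_rate)
    return pos


def _one_hot(codes: np.ndarray) -> np.ndarray:
    return np.eye(4, dtype=np.float32)[codes]


def generate_domain(config: SynthConfig, domain_id: int) -> SynthDataset:
    """Generate one domain; deterministic in (config.seed, domain_id)."""
    if domain_id not in (0, 1):
        raise ValueError("domain_id must be 0 (source) or 1 (target)")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101, domain_id]))
    n = config.n_pairs_per_domain
    n_pos = round(n * config.label_balance)
    labels = np.zeros(n, dtype=np.int8)
    labels[:n_pos] = 1
    gc = config.background_gc[domain_id]
    base_p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    enh_codes = rng.choice(4, size=(n, config.enh_len), p=base_p).astype(np.int8)
    prom_codes = rng.choice(4, size=(n, config.prom_len), p=base_p).astype(np.int8)

    # decoys first, so the label-defining motifs stay intact if they collide
    for decoy in config.decoy_motifs[domain_id]:
        dc = np.array([_CODE[b] for b in decoy], dtype=np.int8)
        for arr, L in ((enh_codes, config.enh_len), (prom_codes, config.prom_len)):
            if len(decoy) > L:
                raise ValueError(f"decoy {decoy!r} longer than sequence length {L}")
            hits = rng.random(n) < config.decoy_insertion_prob
            for i in np.nonzero(hits)[0]:
                # decoys are planted at the same copy number as true motifs
                for _ in range(config.n_motif_copies):
                    pos = int(rng.integers(0, L - dc.size + 1))
                    arr[i, pos : pos + dc.size] = dc

    em = np.array([_CODE[b] for b in config.enh_motif], dtype=np.int8)
    pm = np.array([_CODE[b] for b in config.prom_motif], dtype=np.int8)
    enh_pos = np.full(n, -1, dtype=np.int64)
    prom_pos = np.full(n, -1, dtype=np.int64)
    k = config.n_motif_copies
    for i in range(n):
        if labels[i] == 1:
            if rng.random() < config.motif_insertion_prob_positive:
                enh_pos[i] = _plant(enh_codes[i], em, config.enh_len, rng, config.motif_mut_rate, k)
                prom_pos[i] = _plant(prom_codes[i], pm, config.prom_len, rng, config.motif_mut_rate, k)
        elif rng.random() < config.motif_insertion_prob_negative:
            # negatives carry at most one of the two motifs, so co-occurrence
            # — not either motif alone — defines the label
            if rng.random() < 0.5:
                enh_pos[i] = _plant(enh_codes[i], em, config.enh_len, rng, config.motif_mut_rate, k)
            else:
                prom_pos[i] = _plant(prom_codes[i], pm, config.prom_len, rng, config.motif_mut_rate, k)

    perm = rng.permutation(n)
    return SynthDataset(
        enh=_one_hot(enh_codes[perm]),
        prom=_one_hot(prom_codes[perm]),
        epi_label=labels[perm],
        domain_label=domain_id,
        enh_motif_pos=enh_pos[perm],
        prom_motif_pos=prom_pos[perm],
        manifest=config.manifest(domain_id),
    )


def decode_dataset(ds: SynthDataset) -> list[tuple[str, str]]:
    """Decode one-hot arrays back to (enh, prom) strings."""
    out = []
    for i in range(ds.n):
        enh = "".join(_BASES[ds.enh[i].argmax(axis=1)])
        prom = "".join(_BASES[ds.prom[i].argmax(axis=1)])
        out.append((enh, prom))
    return out


def scan_labels(ds: SynthDataset, config: SynthConfig) -> np.ndarray:
    """Label recovery by exact consensus scan: positive iff both motifs occur."""
    pred = np.zeros(ds.n, dtype=np.int8)
    for i, (enh, prom) in enumerate(decode_dataset(ds)):
        pred[i] = int(config.enh_motif in enh and config.prom_motif in prom)
    return pred


# ---------------------------------------------------------------------------
# domain-shift probe
# ---------------------------------------------------------------------------


def _kmer_features(seqs: Sequence[tuple[str, str]], k: int = 3) -> np.ndarray:
    """Per-sample k-mer frequency vector over the concatenated pair."""
    idx = {"".join(km): j for j, km in enumerate(__import__("itertools").product("ACGT", repeat=k))}
    X = np.zeros((len(seqs), len(idx)), dtype=np.float64)
    for i, (enh, prom) in enumerate(seqs):
        s = enh + prom
        for j in range(len(s) - k + 1):
            col = idx.get(s[j : j + k])
            if col is not None:
                X[i, col] += 1
        X[i] /= max(1, len(s) - k + 1)
    return X


def domain_shift_probe(dataset_source: SynthDataset, dataset_target: SynthDataset, seed: int = 0) -> float:
    """Held-out accuracy of a k-mer logistic regression separating domains.

    ~0.5 means the configured shift is undetectable; values near 1 certify a
    strong shift.  Symmetric in the domain order: each domain contributes its
    first half to training and its second half to the held-out evaluation, so
    swapping the arguments only flips the (symmetric) class labels.
    """
    Xs = _kmer_features(decode_dataset(dataset_source))
    Xt = _kmer_features(decode_dataset(dataset_target))
    return _half_split_probe(Xs, Xt)


def _half_split_probe(features_a: np.ndarray, features_b: np.ndarray) -> float:
    from sklearn.linear_model import LogisticRegression

    ha, hb = len(features_a) // 2, len(features_b) // 2
    Xtr = np.vstack([features_a[:ha], features_b[:hb]])
    ytr = np.r_[np.zeros(ha), np.ones(hb)]
    Xte = np.vstack([features_a[ha:], features_b[hb:]])
    yte = np.r_[np.zeros(len(features_a) - ha), np.ones(len(features_b) - hb)]
    clf = LogisticRegression(max_iter=1000)
    clf.fit(Xtr, ytr)
    return float(clf.score(Xte, yte))


# ---------------------------------------------------------------------------
# on-disk genome fixture
# ---------------------------------------------------------------------------


@dataclass
class GenomeFixture:
    genome_path: Path
    enhancer_bed: Path
    promoter_bed: Path
    pairs_tsv: Path
    manifest_path: Path
    manifest: dict


def generate_genome_fixture(seed: int, out_dir) -> GenomeFixture:
    """Write a toy genome + annotations whose pair distances straddle the
    10 kb and 2 Mb filter bounds; the manifest records how many planted pairs
    survive the strict filter (generator-side bookkeeping, computed from the
    planted coordinates alone).

    chr1 (~200 kb) holds the bulk of the pairs, including boundary cases at
    exactly 10 kb, near-chromosome-end elements (exercising N padding), one
    duplicated pair (exercising deduplication) and one cross-chromosome pair;
    chr2 (2.05 Mb, written sparsely) holds pairs at and just under 2 Mb.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 202]))

    chr1_len = 200_000
    chr2_len = 2_050_000
    chr1 = "".join(_BASES[rng.choice(4, size=chr1_len)])
    chr2 = "".join(_BASES[rng.choice(4, size=chr2_len)])

    # promoters on chr1 (width 1000, centers at start+500)
    prom_centers = [30_000, 100_000, 170_000]
    promoters = [("chr1", c - 500, c + 500) for c in prom_centers]
    # one promoter near the chr1 end: its 2 kb window needs right padding
    promoters.append(("chr1", chr1_len - 600, chr1_len - 100))  # center 199650
    # chr2 promoters for the 2 Mb bound
    promoters.append(("chr2", 2_024_500, 2_025_500))  # center 2,025,000
    promoters.append(("chr2", 2_019_500, 2_020_500))  # center 2,020,000
    promoters.append(("chr2", 1_899_500, 1_900_500))  # center 1,900,000

    # enhancers (width 400, center start+200)
    enh_centers_chr1 = [
        200,      # near chromosome start -> left N padding in a 3 kb window
        19_800,   # d=10,200 to prom 30k (kept)
        20_000,   # d=10,000 exactly (removed, strict bound)
        45_000,   # d=15,000 to prom 30k / 55,000 to prom 100k
        60_000,   # d=30,000 / 40,000
        80_000,   # d=20,000
        130_000,  # d=30,000 to prom 100k / 40,000 to prom 170k
        150_000,  # d=20,000
        199_800,  # near chromosome end
    ]
    # candidate-only enhancers left of the 100 kb promoter: a dense ladder of
    # distances so every quantile bin of the positives has non-interacting
    # candidates to subsample from
    candidate_offsets = [
        10_500, 11_000, 13_000, 16_000, 18_000, 19_000, 19_500,
        21_000, 25_000, 28_000, 29_500, 29_900, 30_000, 31_000, 35_000, 45_000,
    ]
    enh_centers_chr1 += [100_000 - off for off in candidate_offsets]
    enhancers = [("chr1", c - 200, c + 200) for c in enh_centers_chr1]
    enhancers.append(("chr2", 24_800, 25_200))  # center 25,000
    enhancers.append(("chr2", 29_800, 30_200))  # center 30,000 (candidates near 2 Mb)

    pair_plan = [
        # (enh_center, prom_center, chrom pair, label)
        (("chr1", 19_800), ("chr1", 30_000), 1),   # d=10,200 kept
        (("chr1", 20_000), ("chr1", 30_000), 1),   # d=10,000 removed (strict)
        (("chr1", 45_000), ("chr1", 30_000), 1),   # d=15,000 kept
        (("chr1", 45_000), ("chr1", 100_000), 0),  # d=55,000 kept
        (("chr1", 60_000), ("chr1", 30_000), 1),   # d=30,000 kept
        (("chr1", 60_000), ("chr1", 100_000), 0),  # d=40,000 kept
        (("chr1", 80_000), ("chr1", 100_000), 1),  # d=20,000 kept
        (("chr1", 130_000), ("chr1", 100_000), 1), # d=30,000 kept
        (("chr1", 130_000), ("chr1", 170_000), 0), # d=40,000 kept
        (("chr1", 150_000), ("chr1", 170_000), 1), # d=20,000 kept
        (("chr1", 150_000), ("chr1", 170_000), 1), # duplicate planted on purpose
        (("chr1", 200), ("chr1", 30_000), 1),      # d=29,800 kept; left padding
        (("chr1", 199_800), ("chr1", 199_650), 0), # d=150 removed (< 10 kb)
        (("chr1", 199_800), ("chr2", 2_025_000), 0),  # cross-chromosome, removed
        (("chr2", 25_000), ("chr2", 2_025_000), 1),   # d=2,000,000 removed (strict)
        (("chr2", 25_000), ("chr2", 2_020_000), 1),   # d=1,995,000 kept
    ]

    enh_by_center = {(e[0], (e[1] + e[2]) // 2): e for e in enhancers}
    prom_by_center = {(p[0], (p[1] + p[2]) // 2): p for p in promoters}

    rows = []
    n_surviving = 0
    n_surviving_unique = 0
    seen = set()
    for enh_key, prom_key, label in pair_plan:
        e = enh_by_center[enh_key]
        p = prom_by_center[prom_key]
        same = e[0] == p[0]
        d = abs(((p[1] + p[2]) // 2) - ((e[1] + e[2]) // 2)) if same else None
        survives = same and 10_000 < d < 2_000_000
        if survives:
            n_surviving += 1
            key = e + p
            if key not in seen:
                seen.add(key)
                n_surviving_unique += 1
        rows.append((e, p, label))

    genome_path = out_dir / "genome.fa"
    with open(genome_path, "w") as fh:
        for name, seq in (("chr1", chr1), ("chr2", chr2)):
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")

    enhancer_bed = out_dir / "enhancers.bed"
    with open(enhancer_bed, "w") as fh:
        for chrom, s, e in enhancers:
            fh.write(f"{chrom}\t{s}\t{e}\n")
    promoter_bed = out_dir / "promoters.bed"
    with open(promoter_bed, "w") as fh:
        for chrom, s, e in promoters:
            fh.write(f"{chrom}\t{s}\t{e}\n")
    pairs_tsv = out_dir / "pairs.tsv"
    with open(pairs_tsv, "w") as fh:
        for (ec, es, ee), (pc, ps, pe), label in rows:
            fh.write(f"{ec}\t{es}\t{ee}\t{pc}\t{ps}\t{pe}\t{label}\n")

    manifest = {
        "seed": int(seed),
        "chromosomes": {"chr1": chr1_len, "chr2": chr2_len},
        "n_pairs_written": len(rows),
        "n_surviving_distance_filter": n_surviving,
        "n_surviving_unique": n_surviving_unique,
        "min_distance": 10_000,
        "max_distance": 2_000_000,
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return GenomeFixture(genome_path, enhancer_bed, promoter_bed, pairs_tsv, manifest_path, manifest)


def benchmark_domains(config: SynthConfig):
    """Generate (source, target_train, target_test) domain datasets.

    The target domain is split half/half at random (seeded from the config);
    the training half is stripped of interaction labels, mirroring the
    no-labels-in-the-new-cell-line assumption.
    """
    source = generate_domain(config, 0).to_domain_dataset("source")
    target = generate_domain(config, 1)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    order = rng.permutation(target.n)
    half = target.n // 2
    t_all = target.to_domain_dataset("target_test")
    target_train = DomainDataset(
        t_all.enh[order[:half]], t_all.prom[order[:half]], None, 1, "target_train", t_all.cell_lines
    )
    target_test = t_all.subset(order[half:])
    return source, target_train, target_test
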