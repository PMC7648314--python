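"""Corpus construction for cross-cell-line EPI prediction.

Positive enhancer-promoter pairs come from chromatin-contact annotation; this
module turns them into balanced, distance-matched training corpora:

* strict genomic-distance filter (default: more than 10 kb and less than 2 Mb
  between element centers, same chromosome);
* quantile discretization of the positive distance distribution into bins
  (default 5), so negatives can be matched to the positive distance profile;
* per-bin subsampling of random non-interacting candidates to exactly the
  positive count, removing distance as a trivial discriminative signal;
* assembly of a labeled source domain (pooled cell lines, domain label 0) and
  an unlabeled target domain (the held-out cell line, domain label 1) with a
  random half/half train/test split of the target.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .genomic import GenomicRegion

MIN_DISTANCE = 10_000
MAX_DISTANCE = 2_000_000
N_BINS = 5


class SamplingError(RuntimeError):
    """A bin has fewer negative candidates than positives."""


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class EPIPair:
    """An enhancer-promoter pair, optionally labeled."""

    enhancer: GenomicRegion
    promoter: GenomicRegion
    epi_label: Optional[int] = None
    cell_line: str = ""
    bin_id: Optional[int] = None

    @property
    def distance(self) -> Optional[int]:
        """Center-to-center distance; None for cross-chromosome pairs."""
        if self.enhancer.chrom != self.promoter.chrom:
            return None
        return abs(self.promoter.center - self.enhancer.center)

    def coords(self):
        return self.enhancer.coords() + self.promoter.coords()


@dataclass
class DomainDataset:
    """Stacked one-hot arrays for one domain role.

    ``epi_label`` is None for the unlabeled target training split; the domain
    label is 0 for source and 1 for target samples.
    """

    enh: np.ndarray  # (n, enh_len, 4)
    prom: np.ndarray  # (n, prom_len, 4)
    epi_label: Optional[np.ndarray]  # (n,) int8 or None
    domain_label: int
    role: str  # "source" | "target_train" | "target_test"
    cell_lines: tuple[str, ...] = ()

    def __post_init__(self):
        if self.role not in ("source", "target_train", "target_test"):
            raise ConfigurationError(f"unknown role {self.role!r}")
        if self.role == "source" and self.epi_label is None:
            raise ConfigurationError("source domain requires EPI labels")

    @property
    def n(self) -> int:
        return self.enh.shape[0]

    def subset(self, idx) -> "DomainDataset":
        labels = None if self.epi_label is None else self.epi_label[idx]
        return DomainDataset(self.enh[idx], self.prom[idx], labels, self.domain_label, self.role, self.cell_lines)


# ---------------------------------------------------------------------------
# distance filtering and binning
# ---------------------------------------------------------------------------


def filter_by_distance(pairs: Sequence[EPIPair], min_d: int = MIN_DISTANCE, max_d: int = MAX_DISTANCE) -> list[EPIPair]:
    """Keep pairs with min_d < distance < max_d (strict); drop cross-chromosome pairs."""
    out = []
    for p in pairs:
        d = p.distance
        if d is not None and min_d < d < max_d:
            out.append(p)
    return out


def assign_quantile_bins(positives: Sequence[EPIPair], n_bins: int = N_BINS) -> tuple[list[EPIPair], np.ndarray]:
    """Bin positives by distance quantiles; returns (binned positives, edges).

    Edges are the empirical distance quantiles at k/n_bins (k = 1..n_bins-1)
    of the *positive* pairs; negatives are later binned with these same edges.
    Values equal to an edge fall in the lower bin.
    """
    if n_bins < 1:
        raise ConfigurationError(f"n_bins must be >= 1, got {n_bins}")
    if len(positives) < n_bins:
        raise ConfigurationError(f"need at least {n_bins} positives to form {n_bins} bins, got {len(positives)}")
    distances = np.array([p.distance for p in positives], dtype=float)
    if np.any(np.isnan(distances)):
        raise ConfigurationError("positives must pass the distance filter before binning")
    edges = np.quantile(distances, np.arange(1, n_bins) / n_bins)
    binned = [replace(p, bin_id=int(np.searchsorted(edges, p.distance, side="left"))) for p in positives]
    return binned, edges


def bin_of(distance: float, edges: np.ndarray) -> int:
    return int(np.searchsorted(edges, distance, side="left"))


def subsample_negatives(
    positives: Sequence[EPIPair],
    candidates: Sequence[EPIPair],
    edges: np.ndarray,
    seed: int,
) -> list[EPIPair]:
    """Draw, per distance bin, as many negatives as there are positives.

    Sampling is uniform without replacement and deterministic for a given
    seed.  Raises :class:`SamplingError` naming the first deficient bin.
    """
    n_bins = len(edges) + 1
    pos_counts = np.zeros(n_bins, dtype=int)
    for p in positives:
        if p.bin_id is None:
            raise ConfigurationError("positives must carry bin_id (run assign_quantile_bins first)")
        pos_counts[p.bin_id] += 1
    by_bin: list[list[EPIPair]] = [[] for _ in range(n_bins)]
    for c in candidates:
        d = c.distance
        if d is None:
            continue
        by_bin[bin_of(d, edges)].append(c)
    rng = np.random.default_rng(seed)
    negatives: list[EPIPair] = []
    for b in range(n_bins):
        need = int(pos_counts[b])
        pool = by_bin[b]
        if need == 0:
            continue
        if len(pool) < need:
            raise SamplingError(f"bin {b}: {len(pool)} candidates < {need} positives")
        chosen = rng.choice(len(pool), size=need, replace=False)
        negatives.extend(replace(pool[i], epi_label=0, bin_id=b) for i in sorted(chosen))
    return negatives


def generate_negative_candidates(
    enhancers: Sequence[GenomicRegion],
    promoters: Sequence[GenomicRegion],
    positives: Sequence[EPIPair],
    min_d: int = MIN_DISTANCE,
    max_d: int = MAX_DISTANCE,
    cell_line: str = "",
) -> list[EPIPair]:
    """All enhancer x promoter pairs passing the distance filter that are not
    labeled positive.  Streams chromosome by chromosome to bound memory."""
    positive_keys = {p.coords() for p in positives}
    enh_by_chrom: dict[str, list[GenomicRegion]] = {}
    for e in enhancers:
        enh_by_chrom.setdefault(e.chrom, []).append(e)
    out: list[EPIPair] = []
    for prom in promoters:
        for enh in enh_by_chrom.get(prom.chrom, ()):
            if not (min_d < abs(prom.center - enh.center) < max_d):
                continue
            if enh.coords() + prom.coords() in positive_keys:
                continue
            out.append(EPIPair(enhancer=enh, promoter=prom, epi_label=0, cell_line=cell_line))
    return out


# ---------------------------------------------------------------------------
# overlap accounting and domain assembly
# ---------------------------------------------------------------------------


def count_epi_overlap(set_a: Sequence[EPIPair], set_b: Sequence[EPIPair]) -> int:
    """Pairs of set_a whose enhancer AND promoter coordinates match exactly
    (chrom, start, end of both elements) some pair of set_b."""
    keys_b = {p.coords() for p in set_b}
    return sum(1 for p in set_a if p.coords() in keys_b)


def dedupe_pairs(pairs: Sequence[EPIPair]) -> list[EPIPair]:
    """Drop duplicate pairs (exact element coordinates), keeping first occurrence."""
    seen = set()
    out = []
    for p in pairs:
        k = p.coords()
        if k not in seen:
            seen.add(k)
            out.append(p)
    return out


def split_pairs(pairs: Sequence[EPIPair], seed: int) -> tuple[list[EPIPair], list[EPIPair]]:
    """Random half/half split (first half train, second half test; +-1 for odd n)."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pairs))
    half = len(pairs) // 2
    train = [pairs[i] for i in order[:half]]
    test = [pairs[i] for i in order[half:]]
    return train, test


def build_domains(
    cell_line_tables: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
    target_cell: str,
    split_seed: int,
) -> tuple[DomainDataset, DomainDataset, DomainDataset]:
    """Assemble source / target_train / target_test domain datasets.

    ``cell_line_tables`` maps cell line name to (enh, prom, epi_label) arrays
    of balanced labeled samples.  The target cell line is split half/half at
    random; its training half is stripped of EPI labels (they are unknown at
    training time by assumption) and both halves get domain label 1.  All
    remaining cell lines are concatenated, shuffled, and form the source
    domain with domain label 0.
    """
    if target_cell not in cell_line_tables:
        raise ConfigurationError(f"target cell {target_cell!r} not among {sorted(cell_line_tables)}")
    others = [name for name in cell_line_tables if name != target_cell]
    if not others:
        raise ConfigurationError("need at least one non-target cell line for the source domain")
    rng = np.random.default_rng(split_seed)

    t_enh, t_prom, t_lab = cell_line_tables[target_cell]
    order = rng.permutation(t_enh.shape[0])
    half = t_enh.shape[0] // 2
    tr, te = order[:half], order[half:]
    target_train = DomainDataset(t_enh[tr], t_prom[tr], None, 1, "target_train", (target_cell,))
    target_test = DomainDataset(t_enh[te], t_prom[te], np.asarray(t_lab)[te], 1, "target_test", (target_cell,))

    enh = np.concatenate([cell_line_tables[n][0] for n in others])
    prom = np.concatenate([cell_line_tables[n][1] for n in others])
    lab = np.concatenate([np.asarray(cell_line_tables[n][2]) for n in others])
    order = rng.permutation(enh.shape[0])
    source = DomainDataset(enh[order], prom[order], lab[order], 0, "source", tuple(others))
    return source, target_train, target_test
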