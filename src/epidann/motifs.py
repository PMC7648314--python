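"""Interpreting first-layer convolution kernels as sequence motifs.

For each kernel, the best-matching (maximally activating, pre-ReLU)
kernel-length subsequence is extracted from every input sequence whose
maximum activation is positive; the aligned subsequences yield a position
frequency matrix (PFM).  PFMs are exported in MEME minimal motif format for
downstream matching against motif databases, and two trained models (with and
without domain-adversarial transfer) are compared by a relative importance
score:

    importance = (1 - N_wo / N_w) / Rank_w

where N_w and N_wo are how often a motif occurs among the kernels of the
with-transfer and without-transfer model respectively, and Rank_w is the
motif's rank (descending, ties sharing the minimum rank) by N_w.  Scores near
1 flag motifs the transfer model relies on that the plain model does not.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

_BASES = "ACGT"


@dataclass
class PFM:
    kernel_id: int
    counts: np.ndarray  # (kernel_len, 4) nonnegative ints, columns A,C,G,T
    n_sequences: int
    branch: str = ""

    @property
    def consensus(self) -> str:
        # argmax ties resolve to A<C<G<T order (np.argmax takes the first)
        return "".join(_BASES[i] for i in self.counts.argmax(axis=1))

    @property
    def probabilities(self) -> np.ndarray:
        return self.counts / self.n_sequences


@dataclass
class MotifImportance:
    motif_id: str
    n_with: int
    n_without: int
    rank_with: int
    score: float


def best_subsequence(kernel_id: int, sequence: str, activations: np.ndarray, kernel_len: int) -> Optional[str]:
    """The kernel-length window at the position of maximum activation.

    ``activations`` is the (L-K+1, n_kernels) linear first-layer output for
    this sequence.  Returns None (skip) when the maximum activation is <= 0;
    ties go to the leftmost position.
    """
    if not 0 <= kernel_id < activations.shape[1]:
        raise IndexError(f"kernel_id {kernel_id} out of range [0, {activations.shape[1]})")
    acts = activations[:, kernel_id]
    pos = int(np.argmax(acts))  # leftmost maximum
    if acts[pos] <= 0:
        return None
    return sequence[pos : pos + kernel_len]


def build_pfm(subsequences: Sequence[str], kernel_id: int = 0, branch: str = "") -> PFM:
    """Per-position base counts over aligned equal-length subsequences."""
    if not subsequences:
        raise ValueError("cannot build a PFM from zero subsequences")
    length = len(subsequences[0])
    counts = np.zeros((length, 4), dtype=np.int64)
    for s in subsequences:
        if len(s) != length:
            raise ValueError(f"subsequence length {len(s)} != {length}")
        for i, ch in enumerate(s):
            counts[i, _BASES.index(ch)] += 1
    return PFM(kernel_id=kernel_id, counts=counts, n_sequences=len(subsequences), branch=branch)


def extract_kernel_pfms(network, sequences: Sequence[str], branch: str = "enhancer") -> list[PFM]:
    """One PFM per first-layer kernel from its best-matching subsequences.

    Sequences containing 'N' inside the selected window are excluded, so PFM
    column sums equal the number of admitted subsequences.
    """
    from .genomic import one_hot_encode

    onehot = np.stack([one_hot_encode(s) for s in sequences])
    acts = network.first_layer_activations(onehot, branch)  # (B, L-K+1, K)
    klen = network.config.kernel_len
    pfms = []
    for k in range(acts.shape[2]):
        subs = []
        for i, seq in enumerate(sequences):
            sub = best_subsequence(k, seq, acts[i], klen)
            if sub is not None and "N" not in sub:
                subs.append(sub)
        if subs:
            pfms.append(build_pfm(subs, kernel_id=k, branch=branch))
    return pfms


def write_meme(pfms: Sequence[PFM], path, background: Sequence[float] = (0.25, 0.25, 0.25, 0.25)) -> int:
    """Write PFMs in MEME minimal motif format; returns motifs written.

    Zero-count PFMs are skipped with a warning.  Probabilities are
    counts / n_sequences; ``nsites`` records the subsequence count.
    """
    import warnings

    bg = np.asarray(background, dtype=float)
    if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0):
        raise ValueError("background must be 4 probabilities summing to 1")
    written = 0
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(f"A {bg[0]:.5f} C {bg[1]:.5f} G {bg[2]:.5f} T {bg[3]:.5f}\n\n")
        for pfm in pfms:
            if pfm.n_sequences <= 0 or pfm.counts.sum() == 0:
                warnings.warn(f"skipping zero-count PFM for kernel {pfm.kernel_id}")
                continue
            name = f"{pfm.branch + '_' if pfm.branch else ''}kernel_{pfm.kernel_id}"
            fh.write(f"MOTIF {name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pfm.counts.shape[0]} "
                f"nsites= {pfm.n_sequences} E= 0\n"
            )
            for row in pfm.probabilities:
                fh.write(" " + " ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")
            written += 1
    return written


def relative_importance(n_with: int, n_without: int, rank_with: int) -> float:
    """(1 - N_wo/N_w) / Rank_w; maximal (1.0) for a rank-1 motif absent from
    the no-transfer model."""
    if n_with <= 0:
        raise ValueError("N_w must be positive")
    if rank_with < 1:
        raise ValueError("rank must be >= 1")
    return (1.0 - n_without / n_with) / rank_with


def _min_ranks(counts: Mapping[str, int]) -> dict[str, int]:
    """Descending rank by count; ties share the minimum rank."""
    return {m: 1 + sum(1 for c in counts.values() if c > n) for m, n in counts.items()}


def compare_models(
    with_model_motifs: Sequence[Sequence[str]],
    without_model_motifs: Sequence[Sequence[str]],
    top_k: Optional[int] = None,
) -> list[MotifImportance]:
    """Rank motifs by relative importance between two models.

    Each argument is a list of repeats (default protocol: 5 independent
    trainings); each repeat is the list of motif identities its kernels
    mapped to.  Occurrence counts aggregate kernels-per-motif across repeats.
    """
    n_w = Counter()
    for repeat in with_model_motifs:
        n_w.update(repeat)
    n_wo = Counter()
    for repeat in without_model_motifs:
        n_wo.update(repeat)
    if not n_w:
        return []
    ranks = _min_ranks(n_w)
    out = [
        MotifImportance(
            motif_id=m,
            n_with=n_w[m],
            n_without=n_wo.get(m, 0),
            rank_with=ranks[m],
            score=relative_importance(n_w[m], n_wo.get(m, 0), ranks[m]),
        )
        for m in n_w
    ]
    out.sort(key=lambda r: (-r.score, r.rank_with, r.motif_id))
    return out[:top_k] if top_k else out


def consensus_identity(consensus: str, motif: str) -> float:
    """Best positional identity of ``motif`` slid along ``consensus``.

    The shorter string slides inside the longer; identity is matching
    positions over the shorter length, maximized over offsets.
    """
    short, long_ = (motif, consensus) if len(motif) <= len(consensus) else (consensus, motif)
    best = 0.0
    for off in range(len(long_) - len(short) + 1):
        hits = sum(a == b for a, b in zip(short, long_[off : off + len(short)]))
        best = max(best, hits / len(short))
    return best
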