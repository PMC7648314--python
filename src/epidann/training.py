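"""Adversarial training loop.

Each minibatch holds an equal number of source samples (with interaction
labels, domain 0) and target samples (unlabeled, domain 1).  A training step
has two phases:

* phase 1 — the EPI-label loss on the source half updates the extractor and
  the EPI predictor (target labels are never read: the target half carries
  none);
* phase 2 — the domain loss on the full batch updates the discriminator, and
  through the gradient reversal layer pushes the extractor toward features
  the discriminator cannot use.

Both phases use plain SGD at a constant learning rate (default 0.001, 80
epochs, batch 64 — the full-scale settings).  The "source_only" variant skips
phase 2 entirely and ignores target data.

Reproducibility: one seed drives everything, but each consumer (weight init,
source shuffling, target shuffling, per-step dropout per phase) gets its own
SeedSequence-derived stream.  Streams are therefore identical between model
variants that share them — e.g. the full model with lambda = 0 and the
source-only model see bit-identical source batches, initial shared weights
and phase-1 dropout masks, so their extractor/predictor trajectories match
exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .model import ModelConfig, Network
from .nn import binary_cross_entropy
from .pairs import DomainDataset

__all__ = ["TrainConfig", "TrainHistory", "make_minibatch_indices", "train_step", "train"]


@dataclass
class TrainConfig:
    epochs: int = 80
    batch_size: int = 64
    learning_rate: float = 0.001
    seed: int = 0
    log_every: int = 0  # epochs between stderr log lines; 0 = silent

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 2 or self.batch_size % 2 != 0:
            raise ValueError("batch_size must be even (split equally across domains)")


@dataclass
class TrainHistory:
    """One record per completed epoch."""

    epoch: list[int] = field(default_factory=list)
    epi_loss: list[float] = field(default_factory=list)
    domain_loss: list[Optional[float]] = field(default_factory=list)
    seed: int = 0

    def append(self, epoch, epi_loss, domain_loss):
        self.epoch.append(epoch)
        self.epi_loss.append(epi_loss)
        self.domain_loss.append(domain_loss)

    def to_records(self):
        return [
            {"epoch": e, "epi_loss": y, "domain_loss": d}
            for e, y, d in zip(self.epoch, self.epi_loss, self.domain_loss)
        ]


class _IndexStream:
    """Endless shuffled index stream over a dataset; reshuffles on exhaustion."""

    def __init__(self, n: int, rng: np.random.Generator):
        if n == 0:
            raise ValueError("cannot stream from an empty dataset")
        self.n = n
        self.rng = rng
        self._order = rng.permutation(n)
        self._pos = 0

    def take(self, k: int) -> np.ndarray:
        out = []
        while k > 0:
            if self._pos == self.n:
                self._order = self.rng.permutation(self.n)
                self._pos = 0
            grab = min(k, self.n - self._pos)
            out.append(self._order[self._pos : self._pos + grab])
            self._pos += grab
            k -= grab
        return np.concatenate(out)


def make_minibatch_indices(source_stream: _IndexStream, target_stream: Optional[_IndexStream], batch_size: int):
    """Half source, half target indices; target stream may be absent
    (source-only training), in which case the source takes the full half only."""
    half = batch_size // 2
    src = source_stream.take(half)
    tgt = target_stream.take(half) if target_stream is not None else None
    return src, tgt


def _sgd(params, lr):
    for p in params:
        if p.grad is not None:
            p.data -= (lr * p.grad).astype(p.data.dtype)
        p.zero_grad()


def train_step(
    net: Network,
    source: DomainDataset,
    target: Optional[DomainDataset],
    src_idx: np.ndarray,
    tgt_idx: Optional[np.ndarray],
    lr: float,
    dropout_rngs: tuple,
) -> tuple[float, Optional[float]]:
    """One two-phase update; returns (epi loss, domain loss or None)."""
    rng1, rng2 = dropout_rngs
    adversarial = net.config.has_domain_head and target is not None

    # phase 1: label loss on source -> extractor + EPI head
    feats = net.extract_features(source.enh[src_idx], source.prom[src_idx], train=True, rng=rng1)
    probs = net.epi_head(feats, train=True, rng=rng1)
    epi_loss = binary_cross_entropy(probs, source.epi_label[src_idx].astype(np.float32))
    epi_loss.backward()
    _sgd(net.extractor_parameters() + net.epi_parameters(), lr)

    domain_loss_val = None
    if adversarial:
        # phase 2: domain loss on source + target -> discriminator, and
        # (reversed) extractor
        enh = np.concatenate([source.enh[src_idx], target.enh[tgt_idx]])
        prom = np.concatenate([source.prom[src_idx], target.prom[tgt_idx]])
        dlab = np.concatenate(
            [np.zeros(len(src_idx), dtype=np.float32), np.ones(len(tgt_idx), dtype=np.float32)]
        )
        feats = net.extract_features(enh, prom, train=True, rng=rng2)
        dprobs = net.domain_head(feats, train=True, rng=rng2)
        domain_loss = binary_cross_entropy(dprobs, dlab)
        domain_loss.backward()
        _sgd(net.extractor_parameters() + net.domain_parameters(), lr)
        domain_loss_val = float(domain_loss.data)

    if not math.isfinite(float(epi_loss.data)) or (
        domain_loss_val is not None and not math.isfinite(domain_loss_val)
    ):
        raise FloatingPointError(
            f"non-finite loss (epi={float(epi_loss.data)}, domain={domain_loss_val})"
        )
    return float(epi_loss.data), domain_loss_val


def train(
    source: DomainDataset,
    target_train: Optional[DomainDataset],
    model_config: ModelConfig,
    train_config: TrainConfig,
) -> tuple[Network, TrainHistory]:
    """Run the full training procedure and return the trained network.

    Epoch length is ceil(n_source / (batch_size/2)) steps; the (typically
    smaller) target stream recycles with reshuffling.  Deterministic for a
    given seed.
    """
    if source.epi_label is None:
        raise ValueError("source domain must be labeled")
    seed = int(train_config.seed)
    net = Network(model_config, seed=seed)
    # a variant with a domain head trains adversarially only when target data
    # is supplied; without it, phase 2 is skipped (plain supervised training)
    use_target = model_config.has_domain_head and target_train is not None

    src_stream = _IndexStream(source.n, np.random.default_rng(np.random.SeedSequence([seed, 1])))
    tgt_stream = (
        _IndexStream(target_train.n, np.random.default_rng(np.random.SeedSequence([seed, 2])))
        if use_target
        else None
    )
    half = train_config.batch_size // 2
    steps_per_epoch = math.ceil(source.n / half)
    history = TrainHistory(seed=seed)
    step = 0
    for epoch in range(train_config.epochs):
        epi_losses, dom_losses = [], []
        for _ in range(steps_per_epoch):
            src_idx, tgt_idx = make_minibatch_indices(src_stream, tgt_stream, train_config.batch_size)
            rngs = (
                np.random.default_rng(np.random.SeedSequence([seed, 7, step, 0])),
                np.random.default_rng(np.random.SeedSequence([seed, 7, step, 1])),
            )
            ly, ld = train_step(net, source, target_train if use_target else None, src_idx, tgt_idx, train_config.learning_rate, rngs)
            epi_losses.append(ly)
            if ld is not None:
                dom_losses.append(ld)
            step += 1
        history.append(epoch, float(np.mean(epi_losses)), float(np.mean(dom_losses)) if dom_losses else None)
        if train_config.log_every and (epoch + 1) % train_config.log_every == 0:
            import sys

            print(
                f"epoch {epoch + 1}/{train_config.epochs} epi_loss={history.epi_loss[-1]:.4f}"
                + (f" domain_loss={history.domain_loss[-1]:.4f}" if dom_losses else ""),
                file=sys.stderr,
            )
    return net, history
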