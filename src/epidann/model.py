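"""The domain-adversarial EPI network and its ablation variants.

Architecture (full "dann" variant):

* two branches, one per element: valid 1-D convolution over the one-hot
  sequence (300 kernels of length 40 at full scale) -> ReLU -> max-pool
  (length 20, stride 20), optionally stacked twice;
* branch outputs concatenated along the position axis, dropout 0.25;
* an LSTM over the concatenated frame sequence; its last hidden state (100
  units at full scale) is the shared feature vector;
* an EPI predictor head: dense 100 -> ReLU -> dropout 0.5 -> sigmoid;
* a domain discriminator head behind a gradient reversal layer: dense 50 ->
  ReLU -> dropout 0.5 -> sigmoid.

Variants: "source_only" drops the discriminator (no adversary, so target data
is unusable); "base" uses a single conv block per branch and flattens instead
of recurrent fusion; "base_lstm" and "base_fc" use one conv block with LSTM
or dense fusion respectively.

The training objective is E(theta_f, theta_y, theta_d) =
sum_i L_y^i(theta_f, theta_y) - lambda * sum_i L_d^i(theta_f, theta_d),
optimized to a saddle point: the label loss is minimized over extractor and
predictor weights while the reversal layer makes the extractor *maximize* the
domain loss that the discriminator minimizes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from typing import Optional

import numpy as np

from .nn import (
    LSTM,
    Conv1DLayer,
    Dense,
    Tensor,
    concat,
    dropout,
    grad_scale,
    layer_rng,
    maxpool1d,
    relu,
    sigmoid,
)

logger = logging.getLogger(__name__)

VARIANTS = ("dann", "source_only", "base", "base_lstm", "base_fc")
_SINGLE_BLOCK_VARIANTS = ("base", "base_lstm", "base_fc")


@dataclass
class ModelConfig:
    variant: str = "dann"
    enh_len: int = 3000
    prom_len: int = 2000
    n_kernels: int = 300
    kernel_len: int = 40
    pool_len: int = 20
    pool_stride: int = 20
    n_conv_layers: int = 2
    conv_dropout: float = 0.25
    lstm_dim: int = 100
    epi_dense_dim: int = 100
    domain_dense_dim: int = 50
    head_dropout: float = 0.5
    lambda_grl: float = 1.0
    # Flip to False for the diagnostic control in which the extractor
    # *cooperates* with the domain discriminator (gradient scaled +lambda
    # instead of -lambda). Only meaningful for variants with a domain head.
    reverse_gradient: bool = True

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        for name in ("enh_len", "prom_len", "n_kernels", "kernel_len", "pool_len", "lstm_dim", "epi_dense_dim", "domain_dense_dim"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.pool_stride != self.pool_len:
            raise ValueError("only pool_stride == pool_len is supported")
        if self.lambda_grl < 0:
            raise ValueError("lambda_grl must be >= 0")
        if self.n_conv_layers not in (1, 2):
            raise ValueError("n_conv_layers must be 1 or 2")
        if self.variant in _SINGLE_BLOCK_VARIANTS and self.n_conv_layers != 1:
            logger.warning("variant %r uses a single conv block; n_conv_layers=%d ignored", self.variant, self.n_conv_layers)
        if self.variant == "base":
            logger.warning("variant 'base' has no LSTM/FC fusion; lstm_dim ignored")

    @property
    def conv_blocks(self) -> int:
        return 1 if self.variant in _SINGLE_BLOCK_VARIANTS else self.n_conv_layers

    @property
    def fusion(self) -> str:
        if self.variant == "base":
            return "flatten"
        if self.variant == "base_fc":
            return "dense"
        return "lstm"

    @property
    def has_domain_head(self) -> bool:
        return self.variant != "source_only"


def branch_frame_counts(config: ModelConfig) -> dict[str, list[int]]:
    """Frames per branch after each conv+pool block (valid conv, stride 1).

    E.g. a 3000-nt enhancer with kernel 40 gives 3000-40+1 = 2961 positions,
    pooled 20/20 -> 148 frames; a 2000-nt promoter -> 1961 -> 98 frames.
    """
    out = {}
    for name, length in (("enhancer", config.enh_len), ("promoter", config.prom_len)):
        frames = []
        L = length
        for _ in range(config.conv_blocks):
            conv_out = L - config.kernel_len + 1
            if conv_out < config.pool_len:
                raise ValueError(
                    f"{name} branch collapses: conv output {conv_out} shorter than pool {config.pool_len}"
                )
            L = conv_out // config.pool_len
            frames.append(L)
        out[name] = frames
    return out


def feature_dim(config: ModelConfig) -> int:
    counts = branch_frame_counts(config)
    n_frames = counts["enhancer"][-1] + counts["promoter"][-1]
    if config.fusion == "flatten":
        return n_frames * config.n_kernels
    return config.lstm_dim


class Network:
    """The assembled model graph for one configuration.

    The two heads consume the identical feature vector produced by the shared
    extractor; ``lambda_grl`` only scales the gradient the discriminator sends
    back into the extractor.
    """

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        self.seed = int(seed)
        cfg = config
        k = cfg.n_kernels

        def make_branch(prefix):
            layers = [Conv1DLayer(4, k, cfg.kernel_len, layer_rng(seed, f"{prefix}.conv0"), name=f"{prefix}.conv0")]
            if cfg.conv_blocks == 2:
                layers.append(Conv1DLayer(k, k, cfg.kernel_len, layer_rng(seed, f"{prefix}.conv1"), name=f"{prefix}.conv1"))
            return layers

        self.enh_convs = make_branch("enh")
        self.prom_convs = make_branch("prom")

        self.lstm = None
        self.fusion_dense = None
        if cfg.fusion == "lstm":
            self.lstm = LSTM(k, cfg.lstm_dim, layer_rng(seed, "fusion.lstm"), name="fusion.lstm")
        elif cfg.fusion == "dense":
            counts = branch_frame_counts(cfg)
            flat = (counts["enhancer"][-1] + counts["promoter"][-1]) * k
            self.fusion_dense = Dense(flat, cfg.lstm_dim, layer_rng(seed, "fusion.dense"), name="fusion.dense")

        fdim = feature_dim(cfg)
        self.epi_dense = Dense(fdim, cfg.epi_dense_dim, layer_rng(seed, "epi.dense"), name="epi.dense")
        self.epi_out = Dense(cfg.epi_dense_dim, 1, layer_rng(seed, "epi.out"), name="epi.out")
        self.domain_dense = self.domain_out = None
        if cfg.has_domain_head:
            self.domain_dense = Dense(fdim, cfg.domain_dense_dim, layer_rng(seed, "domain.dense"), name="domain.dense")
            self.domain_out = Dense(cfg.domain_dense_dim, 1, layer_rng(seed, "domain.out"), name="domain.out")

        self.branch_frames_ = branch_frame_counts(cfg)

    # -- parameter groups ----------------------------------------------------
    def extractor_parameters(self):
        params = []
        for layer in self.enh_convs + self.prom_convs:
            params.extend(layer.parameters())
        if self.lstm is not None:
            params.extend(self.lstm.parameters())
        if self.fusion_dense is not None:
            params.extend(self.fusion_dense.parameters())
        return params

    def epi_parameters(self):
        return self.epi_dense.parameters() + self.epi_out.parameters()

    def domain_parameters(self):
        if self.domain_dense is None:
            return []
        return self.domain_dense.parameters() + self.domain_out.parameters()

    def parameters(self):
        return self.extractor_parameters() + self.epi_parameters() + self.domain_parameters()

    # -- forward passes ------------------------------------------------------
    def _branch(self, x: Tensor, convs) -> Tensor:
        h = x
        for conv in convs:
            h = maxpool1d(relu(conv(h)), self.config.pool_len)
        return h

    def extract_features(self, enh, prom, train: bool = False, rng=None) -> Tensor:
        """Map one-hot (B, L, 4) inputs to the shared (B, feature_dim) vector."""
        cfg = self.config
        enh_t = enh if isinstance(enh, Tensor) else Tensor(np.asarray(enh, dtype=np.float32))
        prom_t = prom if isinstance(prom, Tensor) else Tensor(np.asarray(prom, dtype=np.float32))
        he = self._branch(enh_t, self.enh_convs)
        hp = self._branch(prom_t, self.prom_convs)
        h = concat([he, hp], axis=1)  # concatenate along the frame (position) axis
        if train and cfg.conv_dropout > 0:
            h = dropout(h, cfg.conv_dropout, rng)
        if cfg.fusion == "lstm":
            return self.lstm(h)
        flat = h.reshape(h.shape[0], h.shape[1] * h.shape[2])
        if cfg.fusion == "dense":
            return relu(self.fusion_dense(flat))
        return flat

    def _head(self, features, dense, out, train, rng):
        h = relu(dense(features))
        if train and self.config.head_dropout > 0:
            h = dropout(h, self.config.head_dropout, rng)
        return sigmoid(out(h).reshape(features.shape[0]))

    def epi_head(self, features: Tensor, train: bool = False, rng=None) -> Tensor:
        return self._head(features, self.epi_dense, self.epi_out, train, rng)

    def domain_head(self, features: Tensor, train: bool = False, rng=None, reverse: Optional[bool] = None) -> Tensor:
        """Domain probability; gradients into the extractor pass the reversal
        layer (scale -lambda) unless ``reverse=False`` (cooperative control)."""
        if self.domain_dense is None:
            raise ValueError(f"variant {self.config.variant!r} has no domain discriminator")
        if reverse is None:
            reverse = self.config.reverse_gradient
        factor = -self.config.lambda_grl if reverse else self.config.lambda_grl
        feat = grad_scale(features, factor)
        return self._head(feat, self.domain_dense, self.domain_out, train, rng)

    # -- inference -----------------------------------------------------------
    def predict_epi_proba(self, enh, prom, batch_size: int = 256) -> np.ndarray:
        return self._predict(enh, prom, self.epi_head, batch_size)

    def predict_domain_proba(self, enh, prom, batch_size: int = 256) -> np.ndarray:
        if self.domain_dense is None:
            raise ValueError("no domain discriminator in this variant")
        return self._predict(enh, prom, self.domain_head, batch_size)

    def _predict(self, enh, prom, head, batch_size):
        enh = np.asarray(enh, dtype=np.float32)
        prom = np.asarray(prom, dtype=np.float32)
        out = []
        for i in range(0, enh.shape[0], batch_size):
            feats = self.extract_features(enh[i : i + batch_size], prom[i : i + batch_size], train=False)
            out.append(head(feats, train=False).data)
        return np.concatenate(out)

    def transform(self, enh, prom, batch_size: int = 256) -> np.ndarray:
        """Feature vectors with dropout disabled."""
        enh = np.asarray(enh, dtype=np.float32)
        prom = np.asarray(prom, dtype=np.float32)
        out = []
        for i in range(0, enh.shape[0], batch_size):
            out.append(self.extract_features(enh[i : i + batch_size], prom[i : i + batch_size], train=False).data)
        return np.concatenate(out)

    # -- first-layer introspection (motif analysis) --------------------------
    def first_layer_activations(self, seqs_onehot: np.ndarray, branch: str) -> np.ndarray:
        """Linear (pre-ReLU) outputs of the first conv layer, (B, L-K+1, K)."""
        conv = {"enhancer": self.enh_convs, "promoter": self.prom_convs}[branch][0]
        from .nn.autograd import conv1d

        return conv1d(Tensor(np.asarray(seqs_onehot, dtype=np.float32)), conv.w, conv.b).data

    # -- serialization -------------------------------------------------------
    def save(self, path) -> None:
        arrays = {p.name: p.data for p in self.parameters()}
        arrays["__config__"] = np.frombuffer(json.dumps(asdict(self.config)).encode(), dtype=np.uint8)
        arrays["__seed__"] = np.array([self.seed])
        np.savez_compressed(path, **arrays)

    @classmethod
    def load(cls, path) -> "Network":
        with np.load(path) as data:
            cfg = ModelConfig(**json.loads(bytes(data["__config__"]).decode()))
            net = cls(cfg, seed=int(data["__seed__"][0]))
            for p in net.parameters():
                p.data = data[p.name].copy()
        return net


# ---------------------------------------------------------------------------
# objective (reporting form)
# ---------------------------------------------------------------------------


def total_objective(label_losses, domain_losses, lambda_grl: float) -> float:
    """E = sum(L_y) - lambda * sum(L_d), the saddle-point objective."""
    return float(np.sum(label_losses) - lambda_grl * np.sum(domain_losses))


def build_variant(config: ModelConfig, seed: int = 0) -> Network:
    """Construct the network graph for a configuration (thin wrapper)."""
    return Network(config, seed=seed)
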