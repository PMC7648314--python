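"""sklearn-style estimator facade over the domain-adversarial network.

``EPIClassifier`` follows the scikit-learn contract (``get_params`` /
``set_params`` / ``fit`` / ``predict`` / ``predict_proba`` / ``transform``,
fitted attributes with a trailing underscore), so it composes with sklearn
model selection.  ``X`` is the pair of one-hot arrays ``(enh, prom)`` with
shapes (n, enh_len, 4) and (n, prom_len, 4); the unlabeled target-domain
pairs enter as the fit parameter ``X_target``.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .model import ModelConfig, feature_dim
from .pairs import DomainDataset
from .training import TrainConfig, train


def _unpack(X):
    try:
        enh, prom = X
    except (TypeError, ValueError) as exc:
        raise ValueError("X must be a pair (enh, prom) of one-hot arrays") from exc
    enh = np.asarray(enh, dtype=np.float32)
    prom = np.asarray(prom, dtype=np.float32)
    if enh.ndim != 3 or prom.ndim != 3 or enh.shape[2] != 4 or prom.shape[2] != 4:
        raise ValueError(f"expected (n, L, 4) one-hot arrays, got {enh.shape} and {prom.shape}")
    if enh.shape[0] != prom.shape[0]:
        raise ValueError("enhancer and promoter arrays disagree on sample count")
    return enh, prom


class EPIClassifier(ClassifierMixin, BaseEstimator):
    """Cross-cell-line EPI classifier with optional domain-adversarial transfer.

    Parameters mirror the published architecture defaults (300 kernels of
    length 40, pool 20/20, LSTM 100, heads 100/50, dropout 0.25/0.5, SGD at
    0.001 for 80 epochs with batches of 64); scale them down for desk-size
    experiments.

    Examples
    --------
    >>> clf = EPIClassifier(variant="dann", n_kernels=32, kernel_len=12,
    ...                     n_conv_layers=1, lstm_dim=25, epochs=10,
    ...                     learning_rate=0.05, random_state=0)
    >>> clf.fit((enh_src, prom_src), y_src, X_target=(enh_tgt, prom_tgt))
    >>> proba = clf.predict_proba((enh_new, prom_new))[:, 1]
    """

    def __init__(
        self,
        variant: str = "dann",
        n_kernels: int = 300,
        kernel_len: int = 40,
        pool_len: int = 20,
        pool_stride: int = 20,
        n_conv_layers: int = 2,
        conv_dropout: float = 0.25,
        lstm_dim: int = 100,
        epi_dense_dim: int = 100,
        domain_dense_dim: int = 50,
        head_dropout: float = 0.5,
        lambda_grl: float = 1.0,
        reverse_gradient: bool = True,
        epochs: int = 80,
        batch_size: int = 64,
        learning_rate: float = 0.001,
        random_state: Optional[int] = None,
        verbose: int = 0,
    ):
        self.variant = variant
        self.n_kernels = n_kernels
        self.kernel_len = kernel_len
        self.pool_len = pool_len
        self.pool_stride = pool_stride
        self.n_conv_layers = n_conv_layers
        self.conv_dropout = conv_dropout
        self.lstm_dim = lstm_dim
        self.epi_dense_dim = epi_dense_dim
        self.domain_dense_dim = domain_dense_dim
        self.head_dropout = head_dropout
        self.lambda_grl = lambda_grl
        self.reverse_gradient = reverse_gradient
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.random_state = random_state
        self.verbose = verbose

    # -- config assembly -----------------------------------------------------
    def _model_config(self, enh_len, prom_len) -> ModelConfig:
        return ModelConfig(
            variant=self.variant,
            enh_len=enh_len,
            prom_len=prom_len,
            n_kernels=self.n_kernels,
            kernel_len=self.kernel_len,
            pool_len=self.pool_len,
            pool_stride=self.pool_stride,
            n_conv_layers=self.n_conv_layers,
            conv_dropout=self.conv_dropout,
            lstm_dim=self.lstm_dim,
            epi_dense_dim=self.epi_dense_dim,
            domain_dense_dim=self.domain_dense_dim,
            head_dropout=self.head_dropout,
            lambda_grl=self.lambda_grl,
            reverse_gradient=self.reverse_gradient,
        )

    # -- sklearn API ---------------------------------------------------------
    def fit(self, X, y, X_target=None):
        """Train on labeled source pairs, optionally adapting to unlabeled
        target pairs (required for adversarial variants)."""
        enh, prom = _unpack(X)
        y = np.asarray(y)
        if y.shape != (enh.shape[0],):
            raise ValueError(f"y shape {y.shape} does not match {enh.shape[0]} samples")
        if not np.isin(y, (0, 1)).all():
            raise ValueError("y must be binary 0/1")
        source = DomainDataset(enh, prom, y.astype(np.int8), 0, "source")
        target = None
        if X_target is not None:
            t_enh, t_prom = _unpack(X_target)
            target = DomainDataset(t_enh, t_prom, None, 1, "target_train")
        seed = 0 if self.random_state is None else int(self.random_state)
        model_config = self._model_config(enh.shape[1], prom.shape[1])
        train_config = TrainConfig(
            epochs=self.epochs,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            seed=seed,
            log_every=1 if self.verbose else 0,
        )
        self.network_, self.history_ = train(source, target, model_config, train_config)
        self.config_ = model_config
        self.classes_ = np.array([0, 1])
        self.feature_dim_ = feature_dim(model_config)
        return self

    def _check_fitted(self):
        if not hasattr(self, "network_"):
            raise AttributeError("this EPIClassifier instance is not fitted yet")

    def predict_proba(self, X) -> np.ndarray:
        self._check_fitted()
        enh, prom = _unpack(X)
        p1 = self.network_.predict_epi_proba(enh, prom)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def predict_epi_proba(self, enh, prom) -> np.ndarray:
        """Interaction probability from raw arrays (evaluation protocol hook)."""
        self._check_fitted()
        return self.network_.predict_epi_proba(enh, prom)

    def transform(self, X) -> np.ndarray:
        """Shared feature vectors (dropout disabled) — the representation both
        heads consume; useful for domain-invariance probes."""
        self._check_fitted()
        enh, prom = _unpack(X)
        return self.network_.transform(enh, prom)

    def domain_proba(self, X) -> np.ndarray:
        """Discriminator's probability that samples come from the target domain."""
        self._check_fitted()
        enh, prom = _unpack(X)
        return self.network_.predict_domain_proba(enh, prom)
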