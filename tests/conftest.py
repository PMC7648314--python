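import numpy as np
import pytest
from hypothesis import settings

from epidann.pairs import DomainDataset
from epidann.synthetic import SynthConfig, generate_domain

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def tiny_synth_config():
    """Small, fast synthetic configuration shared across tests."""
    return SynthConfig(n_pairs_per_domain=64, enh_len=120, prom_len=80, seed=7)


@pytest.fixture(scope="session")
def tiny_domains(tiny_synth_config):
    """(source, target_train, target_test) at toy scale."""
    src = generate_domain(tiny_synth_config, 0).to_domain_dataset("source")
    tgt = generate_domain(tiny_synth_config, 1)
    t_all = tgt.to_domain_dataset("target_test")
    half = t_all.n // 2
    target_train = DomainDataset(t_all.enh[:half], t_all.prom[:half], None, 1, "target_train")
    target_test = t_all.subset(np.arange(half, t_all.n))
    return src, target_train, target_test


def numeric_gradient(f, param, eps=1e-6):
    """Central finite differences of scalar-valued f() w.r.t. a Tensor param."""
    flat = param.data.reshape(-1)
    grad = np.zeros_like(flat)
    for i in range(flat.size):
        old = flat[i]
        flat[i] = old + eps
        hi = float(f().data)
        flat[i] = old - eps
        lo = float(f().data)
        flat[i] = old
        grad[i] = (hi - lo) / (2 * eps)
    return grad.reshape(param.data.shape)
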