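import numpy as np
import pandas as pd
import pytest

from eqthm.config import SynthConfig
from eqthm.simulate import simulate_dataset


@pytest.fixture(scope="session")
def small_config() -> SynthConfig:
    """A laptop-scale dataset: 60 samples, 15 genes, 300 CpGs."""
    return SynthConfig(n_samples=60, n_genes=15, n_cpgs=300,
                       chrom_length=5_000_000, n_true_eqthm=3, n_true_dhmr=1,
                       seed=42)


@pytest.fixture(scope="session")
def small_data(small_config):
    return simulate_dataset(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def toy_beta_pair(n_probes=10, n_samples=5, seed=0):
    """A small BetaPairMatrix with detection p-values, for QC tests."""
    from eqthm.preprocess import BetaPairMatrix
    r = np.random.default_rng(seed)
    probes = [f"p{i}" for i in range(1, n_probes + 1)]
    samples = [f"S{j}" for j in range(1, n_samples + 1)]
    bs = pd.DataFrame(r.uniform(0.2, 0.8, (n_probes, n_samples)),
                      index=probes, columns=samples)
    oxbs = pd.DataFrame(np.clip(bs.values - r.uniform(0, 0.1, bs.shape), 0, 1),
                        index=probes, columns=samples)
    det = pd.DataFrame(np.full((n_probes, n_samples), 1e-4),
                       index=probes, columns=samples)
    return BetaPairMatrix(bs=bs, oxbs=oxbs, detection_p=det)
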