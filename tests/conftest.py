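import numpy as np
import pytest

import slem
from slem.synthdata import dominant_chain_config


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale planted cohort config used across modules."""
    return slem.SynthConfig(
        n_samples_multilevel=300,
        n_samples_e2e=1500,
        n_snps=20,
        n_isoforms=8,
        n_markers=6,
        n_phenotypes=4,
        effect_size=2.0,
        sparsity=0.1,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    dataset, truth = slem.gen_multilevel(small_config)
    e2e = slem.gen_end_to_end(small_config, truth)
    return dataset, truth, e2e


@pytest.fixture(scope="session")
def small_model(small_cohort):
    dataset, _, _ = small_cohort
    return slem.SLEM.from_multilevel(dataset)


@pytest.fixture(scope="session")
def chain_cohort():
    """Cohort with an explicit dominant SNP chain (snp0000)."""
    cfg = dominant_chain_config(seed=3, n_samples_multilevel=500, n_samples_e2e=3000)
    dataset, truth = slem.gen_multilevel(cfg)
    e2e = slem.gen_end_to_end(cfg, truth)
    return cfg, dataset, truth, e2e


def random_toy_model(rng, sizes=(6, 4, 3, 2, 1), density=0.6):
    """A random masked model for oracle comparisons."""
    labels = []
    prefixes = ("s", "i", "m", "p", "d")
    for k, (pre, n) in enumerate(zip(prefixes, sizes)):
        labels.append(tuple(f"{pre}{j}" for j in range(n)))
    arch = slem.LayerArchitecture(tuple(labels))
    weights, masks = [], []
    for a, b in zip(sizes[:-1], sizes[1:]):
        M = (rng.random((a, b)) < density).astype(np.int8)
        W = rng.normal(size=(a, b)) * M
        weights.append(W)
        masks.append(M)
    return slem.SlemModel(architecture=arch, weights=weights, masks=masks)
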