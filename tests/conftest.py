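import numpy as np
import pandas as pd
import pytest

from prspop.io_formats import GenotypeDataset
from prspop.synthetic_data import (SyntheticConfig, simulate_genotypes,
                                   simulate_prevalence, simulate_summary_stats)


def make_dataset(dosages, positions=None, chrom="1", countries=None,
                 a1="A", a2="G"):
    """Hand-built dataset from a (samples x variants) dosage array."""
    D = np.asarray(dosages, dtype=np.int8)
    n, m = D.shape
    if positions is None:
        positions = 1000 * (np.arange(m) + 1)
    if countries is None:
        countries = ["X"] * n
    variants = pd.DataFrame({
        "id": [f"v{j}" for j in range(m)],
        "chrom": [chrom] * m,
        "pos": positions,
        "a1": [a1] * m,
        "a2": [a2] * m,
    })
    samples = pd.DataFrame({
        "sample": [f"s{i}" for i in range(n)],
        "country": countries,
        "superpop": countries,
    })
    return GenotypeDataset(variants=variants, samples=samples, dosages=D)


@pytest.fixture(scope="session")
def small_world():
    """A small five-population synthetic world with coupled prevalence."""
    cfg = SyntheticConfig(seed=11)
    dataset, truth = simulate_genotypes(cfg)
    stats = simulate_summary_stats(dataset, truth, cfg)
    prevalence = simulate_prevalence(truth, "coupled", seed=12)
    return cfg, dataset, truth, stats, prevalence


@pytest.fixture(scope="session")
def harmonized_world(small_world):
    from prspop.harmonize_qc import harmonize, qc_filter

    cfg, dataset, truth, stats, prevalence = small_world
    qc_ds, _ = qc_filter(dataset)
    pair, _ = harmonize(qc_ds, stats)
    return cfg, qc_ds, truth, pair, prevalence
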