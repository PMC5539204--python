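import numpy as np
import pandas as pd
import pytest

from mirmint.simulate import SyntheticConfig, generate_expression_dataset


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(n_genes=300, n_mirnas=30, frac_de_genes=0.1, frac_de_mirnas=0.2,
                           targets_per_mirna=5, n_gene_sets=12, genes_per_set=10,
                           n_enriched_sets=3, seed=11)


@pytest.fixture(scope="session")
def zero_noise_dataset():
    cfg = SyntheticConfig(n_genes=300, n_mirnas=30, frac_de_genes=0.1, frac_de_mirnas=0.2,
                          targets_per_mirna=5, noise_sd=0.0, prediction_sensitivity=1.0,
                          prediction_fpr=0.0, seed=5)
    genes, mirnas, truth = generate_expression_dataset(cfg)
    return cfg, genes, mirnas, truth


@pytest.fixture()
def two_group_labels():
    def make(n_per_group: int, samples=None):
        if samples is None:
            samples = [f"ct_{i}" for i in range(1, n_per_group + 1)] + [
                f"cc_{i}" for i in range(1, n_per_group + 1)
            ]
        return pd.Series(["control"] * n_per_group + ["case"] * n_per_group, index=samples)

    return make


@pytest.fixture()
def tidy_ct():
    """Build a tidy Ct table from a dict target -> per-sample Ct values."""

    def make(values: dict[str, list[float]], samples=None):
        n = len(next(iter(values.values())))
        if samples is None:
            samples = [f"s{i}" for i in range(1, n + 1)]
        rows = []
        for target, cts in values.items():
            rows += [(samples[i], target, float(cts[i])) for i in range(n)]
        return pd.DataFrame(rows, columns=["sample", "target", "ct"])

    return make


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
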