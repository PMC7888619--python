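import warnings

import numpy as np
import pytest

from titans import synthetic_data as sd
from titans import trio_genotypes as tg


@pytest.fixture(autouse=True)
def _quiet_separation_warnings():
    # tiny fixtures trip separation/empty-window warnings by design
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture(scope="session")
def small_dataset():
    """A 40-trio, 3-gene cohort with one causal gene (ascertained)."""
    cfg = sd.SimulationConfig(n_trios=40, n_snps=4, beta1=0.8, seed=3)
    return sd.simulate_twas_dataset(cfg, n_genes=3)


@pytest.fixture(scope="session")
def dataset_paths(small_dataset, tmp_path_factory):
    out = tmp_path_factory.mktemp("cohort")
    return small_dataset.write(str(out))


def make_matrix(hap_dict, variants=None):
    """Build a PhasedGenotypeMatrix from {sample: [(h1, h2), ...]} by hand."""
    samples = list(hap_dict)
    n_var = len(next(iter(hap_dict.values())))
    if variants is None:
        variants = [tg.VariantRecord("1", i + 1, f"v{i + 1}", "A", "G")
                    for i in range(n_var)]
    haps = np.array([hap_dict[s] for s in samples], dtype=np.int8)
    return tg.PhasedGenotypeMatrix(variants, samples, haps)
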