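import pytest

from ddcm import SyntheticConfig, generate

# desk-scale but small enough that a full screen (1 + 3*M model fits) runs in
# a couple of seconds; 8 diseases supports the j=5 removal regime
SMALL_CONFIG = dict(
    n_diseases=8,
    n_drugs=12,
    n_genes=60,
    n_pathways=24,
    n_clusters=2,
    genes_per_disease=6,
    pathways_per_disease=4,
    targets_per_drug=5,
    pathways_per_drug=4,
    therapeutic_per_disease=1,
)


@pytest.fixture(scope="session")
def small_synth():
    return generate(SyntheticConfig(seed=11, **SMALL_CONFIG))


@pytest.fixture(scope="session")
def small_dataset(small_synth):
    return small_synth.dataset
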