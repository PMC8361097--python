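"""Session-wide synthetic fixtures shared across the suite."""

import pytest

from c3map import codex, signatures, synthetic
from c3map.config import SynthConfig


@pytest.fixture(scope="session")
def tumor_bundle():
    cfg = SynthConfig(seed=11)
    adata, hto, thresholds = synthetic.generate_tumor_cohort(cfg)
    return cfg, adata, hto, thresholds


@pytest.fixture(scope="session")
def tumor(tumor_bundle):
    return tumor_bundle[1]


@pytest.fixture(scope="session")
def tumor_norm(tumor):
    return signatures.normalize_log(tumor)


@pytest.fixture(scope="session")
def tumor_de(tumor_norm):
    return signatures.de_rank_genes(tumor_norm, "subtype")


@pytest.fixture(scope="session")
def normal_norm():
    adata = synthetic.generate_normal_cohort(SynthConfig(seed=12))
    return signatures.normalize_log(adata)


@pytest.fixture(scope="session")
def visium_norm():
    spots = synthetic.generate_visium(SynthConfig(seed=13))
    return signatures.normalize_log(spots)


@pytest.fixture(scope="session")
def codex_cells():
    return synthetic.generate_codex(SynthConfig(seed=14))


@pytest.fixture(scope="session")
def codex_profiles(codex_cells):
    profiles, n_used = codex.neighborhood_profiles(codex_cells)
    return profiles, n_used
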