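import numpy as np
import pytest

import imgomix as im

#: Reduced study for module tests: small enough for sub-second stages but
#: with every planted effect present.
SMALL = dict(
    n_parcels=120, n_genes=300, n_subjects_mdd=60, n_subjects_hc=60,
    n_cpgs=2000, n_pathways=20, n_effect_parcels=10, n_coupled_genes=40,
    n_true_dmps=20, seed=7,
)


@pytest.fixture(scope="session")
def small_study():
    return im.generate_study(im.SynthConfig(**SMALL))


@pytest.fixture(scope="session")
def small_region_results(small_study):
    return im.test_regions(small_study.cohort)


@pytest.fixture(scope="session")
def small_tmap(small_study, small_region_results):
    return im.build_tmap(small_region_results, small_study.parcellation)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
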