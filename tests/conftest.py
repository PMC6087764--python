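import pytest
from hypothesis import settings

from herbnet import (
    NetworkSpec,
    ScreeningCriteria,
    build_bipartite,
    gen_bipartite_edges,
    load_zzw_components,
    load_zzw_targets,
)

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def zzw_components():
    return load_zzw_components()


@pytest.fixture(scope="session")
def zzw_targets():
    return load_zzw_targets()


@pytest.fixture
def default_criteria():
    return ScreeningCriteria()


@pytest.fixture(scope="session")
def synthetic_ct_network():
    """Seeded 61-component / 133-target / 650-edge two-herb network."""
    spec = NetworkSpec(
        n_components_by_herb={"ZHISHI": 44, "BAIZHU": 17},
        n_targets=133,
        n_edges=650,
        seed=7,
    )
    edges, herb_of = gen_bipartite_edges(spec)
    return build_bipartite(edges, herb_of=herb_of)
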