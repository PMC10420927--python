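import pytest

from covkin.synthetic import (
    GeneratorConfig,
    generate_activities,
    generate_library,
    generate_structure_fixtures,
)
from covkin.warheads import load_warhead_library


@pytest.fixture(scope="session")
def warhead_library():
    return load_warhead_library()


@pytest.fixture(scope="session")
def small_dataset():
    """5 cores x 8 substituents with activities, no corruptions."""
    cfg = GeneratorConfig(n_cores=5, substituents_per_core=8, seed=11)
    library = generate_library(cfg)
    records, truth = generate_activities(library, cfg)
    return cfg, library, records, truth


@pytest.fixture(scope="session")
def structure_fixtures(tmp_path_factory):
    out = tmp_path_factory.mktemp("structures")
    manifest = generate_structure_fixtures(out, seed=0)
    return out, manifest
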