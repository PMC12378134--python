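import numpy as np
import pytest

from mibgndb import GeneratorConfig, build_study_ndbs, simulate_study


@pytest.fixture
def rng():
    return np.random.default_rng(2026)


@pytest.fixture
def config():
    return GeneratorConfig(seed=2026)


@pytest.fixture(scope="session")
def small_study():
    """One simulated two-population study shared across read-only tests."""
    cfg = GeneratorConfig(seed=11)
    study = simulate_study(cfg, n_jp_normal=40, n_it_normal=30,
                           n_cad=15, n_dcm=15, n_control=12)
    study["ndbs"] = build_study_ndbs(study["jp_normals"], study["it_normals"])
    return study
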