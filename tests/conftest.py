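import numpy as np
import pytest

import sortscreen as ss


@pytest.fixture(scope="session")
def small_cfg() -> ss.ScreenConfig:
    """100 genes x 6 guides, 50k reads per sample: the counting fixture scale."""
    return ss.ScreenConfig(n_genes=100, sgrnas_per_gene=6, n_nontargeting=0,
                           reads_per_sample=50_000, seed=2024)


@pytest.fixture(scope="session")
def small_lib(small_cfg) -> ss.SgRNALibrary:
    return ss.make_library(small_cfg)


@pytest.fixture(scope="session")
def null_screen() -> ss.ScreenResult:
    """All-neutral screen at the calibration scale (1000 genes x 6 guides)."""
    cfg = ss.ScreenConfig(n_genes=1000, sgrnas_per_gene=6, seed=42)
    return ss.simulate_screen(cfg)


@pytest.fixture(scope="session")
def hit_screen() -> ss.ScreenResult:
    """Screen with 20 planted hit genes (phi=0.3 vs phi0=0.005, eps~Beta(8,2))."""
    cfg = ss.ScreenConfig(n_genes=1000, sgrnas_per_gene=6, seed=11)
    return ss.simulate_screen(cfg, n_hits=20, hit_phi=0.3)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(7)
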