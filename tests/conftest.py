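import numpy as np
import pytest

from hypoxapa.apa_quant import UtrModel
from hypoxapa.syndata import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def utr500() -> UtrModel:
    return UtrModel("T0000", "chr1", 1000, 1500, "+", gene="G0000", breakpoint=200)


@pytest.fixture(scope="session")
def planted_cohort():
    """Default study conditions: n=200, effect 1.0, shift 0.3, 12/38 events."""
    return simulate_cohort(SimConfig(seed=42, n_events=38, n_affected=12))


@pytest.fixture(scope="session")
def null_cohort():
    """No planted effects anywhere."""
    return simulate_cohort(
        SimConfig(seed=7, n_events=38, n_affected=12, hypoxia_effect=0.0,
                  pdui_shift=0.0, hazard_ratio=1.0,
                  stage_advanced_p=(0.4, 0.4), ic50_coupling=0.0,
                  competition_strength=0.0)
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
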