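import numpy as np
import pytest

from surrsupp.observer_model import NormParams, ObserverParams
from surrsupp.psi_staircase import PsiConfig


@pytest.fixture(scope="session")
def psi_config() -> PsiConfig:
    """Default task staircase configuration (tables cached across tests)."""
    cfg = PsiConfig()
    cfg.tables()
    return cfg


@pytest.fixture()
def baseline_observer() -> ObserverParams:
    """Focal-attention, strong-gain-control observer (A_c=2, sigma=0.4)."""
    return ObserverParams(norm=NormParams(a_c=2.0, sigma=0.4),
                          observer_id="base", seed=11)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20230201)
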