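import numpy as np
import pytest

from proctrl.montage import standard_montage
from proctrl.csd import build_basis
from proctrl.design import DesignSpec, generate_design, simulate_behavior, BehaviorParams


@pytest.fixture(scope="session")
def montage():
    return standard_montage()


@pytest.fixture(scope="session")
def basis(montage):
    return build_basis(montage, montage.analysis_labels)


@pytest.fixture(scope="session")
def small_trials():
    """A 36-trial single-hand session with responses filled."""
    spec = DesignSpec(n_blocks=1, trials_per_block=36, hand_switch_block=9, seed=11)
    return simulate_behavior(generate_design(spec), BehaviorParams(seed=12))
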