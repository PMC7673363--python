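import warnings

import numpy as np
import pytest

from airbreath.respirometry import BackgroundModel, ChamberConfig, CyclePlan
from airbreath.synth import EffectConfig, StudyDesign

# mixed-model boundary fits legitimately warn; keep test output readable
from statsmodels.tools.sm_exceptions import ConvergenceWarning  # noqa: E402

warnings.filterwarnings("ignore", category=ConvergenceWarning)
warnings.filterwarnings("ignore", message=".*covariance.*singular.*")
warnings.filterwarnings("ignore", message=".*covariance matrix is singular.*")
warnings.filterwarnings("ignore", message=".*Random effects covariance.*")


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def chamber():
    # 75 mL chamber + 5 mL tubing, 1.65 g fish (volume from mass)
    return ChamberConfig(
        chamber_volume=75.0, tubing_volume=5.0, fish_mass=1.65, channel_id="ch1"
    )


@pytest.fixture
def plan():
    return CyclePlan()


@pytest.fixture
def background():
    return BackgroundModel(
        pre_slope=-0.05, post_slope=-0.15, trial_start=0.0, trial_end=16 * 3600.0
    )


@pytest.fixture
def design_small():
    """Scaled-down factorial design for fast end-to-end tests."""
    return StudyDesign(
        n_groups=2, group_size=3, respirometry_duration_h=1.0, seed=7
    )


@pytest.fixture
def effects_default():
    return EffectConfig()
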