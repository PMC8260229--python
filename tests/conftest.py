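import numpy as np
import pandas as pd
import pytest

from patchforage import (
    PatchGameConfig,
    SyntheticAssayConfig,
    SyntheticTimecourseConfig,
    generate_choice_after_food,
    generate_conditioning_assays,
)


@pytest.fixture
def fig2_config() -> PatchGameConfig:
    """The 9-vs-1 worm, unit-food configuration used throughout the model figures."""
    return PatchGameConfig(n1=9, n2=1, food_per_patch=1.0, switch_cost=0.0)


@pytest.fixture
def assay_table() -> pd.DataFrame:
    return generate_conditioning_assays(
        SyntheticAssayConfig(scenarios={"food+pher": 0.69, "nofood+pher": 0.42}, seed=7)
    )


@pytest.fixture
def timecourse_table() -> pd.DataFrame:
    return generate_choice_after_food(SyntheticTimecourseConfig(seed=7))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
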