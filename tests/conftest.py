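import numpy as np
import pytest

import soundcal as sc


@pytest.fixture(scope="session")
def registry() -> sc.DeviceRegistry:
    return sc.default_registry()


@pytest.fixture(scope="session")
def s7(registry) -> sc.DeviceCalibration:
    """The Galaxy S7 profile: y = 20.5379*log10(x) + 1.3481."""
    cal = registry.resolve("SM-G930F")[1]
    assert cal is not None
    return cal


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)


@pytest.fixture()
def small_db() -> "pd.DataFrame":
    """A small synthetic crowdsensed database covering every status path."""
    spec = sc.DatabaseSpec(
        models=(
            sc.ModelCount("Galaxy S7", 3, 40),
            sc.ModelCount("Galaxy S5", 2, 20),  # mapped but uncalibrated
        ),
        n_ios=25,
        n_no_user_agent=2,
        seed=11,
    )
    return sc.generate_synthetic_database(spec)
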