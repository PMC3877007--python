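import numpy as np
import pandas as pd
import pytest

from chemopanel.synth import PlateDesign


@pytest.fixture
def noise_free_design() -> PlateDesign:
    return PlateDesign(noise_cv=0.0)


@pytest.fixture
def noisy_design() -> PlateDesign:
    return PlateDesign(noise_cv=0.1)


@pytest.fixture
def panel_lines() -> list[str]:
    return [f"L{i + 1:02d}" for i in range(10)]


@pytest.fixture
def potency_row(panel_lines) -> pd.Series:
    rng = np.random.default_rng(42)
    return pd.Series(10.0 ** rng.normal(0.0, 1.0, len(panel_lines)), index=panel_lines)
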