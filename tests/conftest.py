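import numpy as np
import pandas as pd
import pytest

from gazepipe.glmm import BinModelSpec
from gazepipe.sim import simulate_binned_looks


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def cohort_binned():
    """Small cohort-style binned dataset with an effect in bins 4-8."""
    df = simulate_binned_looks(
        14, 10, 12,
        effect_window_bins=(4, 9), effect_logit=0.5,
        baseline_logit=-1.2, subject_sd=0.5, item_sd=0.3, seed=101,
    )
    return df.rename(columns={"look": "competitor_quad"})


@pytest.fixture(scope="session")
def condition_spec():
    return BinModelSpec(
        response="competitor_quad", fixed_effects=("condition",), focal="condition"
    )


@pytest.fixture(scope="session")
def toy_side_binned():
    """2 subjects x 4 trials x 6 bins of side-look indicators with known sides."""
    rng = np.random.default_rng(3)
    rows = []
    for s in range(2):
        for t in range(4):
            side = ["left", "right"][rng.integers(2)]
            for b in range(6):
                p_left = 0.85 if (side == "left" and b >= 2) else (0.15 if b >= 2 else 0.5)
                left = float(rng.random() < p_left)
                rows.append(
                    dict(subject=s, item=t % 2, trial=t, bin=b,
                         left=left, right=1.0 - left,
                         side_look=left if side == "left" else 1.0 - left)
                )
    return pd.DataFrame(rows)
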