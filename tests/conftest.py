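import numpy as np
import pandas as pd
import pytest

import distreg as dr


@pytest.fixture(scope="session")
def rct_data():
    """Small village-randomized scenario without village heterogeneity."""
    df, truth = dr.generate_rct(
        n_villages=20, households_per_village=25, village_sd=0.0, seed=42
    )
    return df, truth


@pytest.fixture(scope="session")
def sm_spec():
    return dr.ModelSpec(
        outcome="y", family="SM",
        formulas={"mu": "1 + treat + povindex", "sigma": "1 + treat",
                  "tau": "1"},
    )


@pytest.fixture(scope="session")
def sm_fit(rct_data, sm_spec):
    df, _ = rct_data
    return dr.fit(sm_spec, df)


@pytest.fixture(scope="session")
def normal_data():
    rng = np.random.default_rng(7)
    n = 400
    x = rng.normal(size=n)
    t = (rng.uniform(size=n) < 0.5).astype(float)
    y = 1.0 + 0.8 * x + 0.5 * t + rng.normal(scale=0.7, size=n)
    return pd.DataFrame({"y": y, "x": x, "treat": t})
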