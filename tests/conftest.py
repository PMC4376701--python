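import numpy as np
import pandas as pd
import pytest

from pearlsex import SimConfig, simulate_ct
from pearlsex.qpcr import relative_expression
from pearlsex.features import ratio_features


@pytest.fixture(scope="session")
def ct_default():
    """Default-noise Ct table + metadata (fixed seed)."""
    return simulate_ct(SimConfig(seed=1))


@pytest.fixture(scope="session")
def ct_noiseless():
    """Zero-noise Ct table: derived ratios sit exactly at design values."""
    return simulate_ct(SimConfig(seed=1, ct_noise_sd=0.0, ct_replicate_sd=0.0))


@pytest.fixture(scope="session")
def rel_default(ct_default):
    ct, _ = ct_default
    return relative_expression(ct)


@pytest.fixture(scope="session")
def feat_default(rel_default):
    return ratio_features(rel_default)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def tiny_relexpr():
    """Four hand-made samples, one per pathway class, on the rule scale."""
    from pearlsex.types import RelExprTable

    rows = {
        # genes: foxl2, c43476, c45042, c19309, c54338, vit6, zglp1, dmrt, fem1-like
        "mp1": [0.01, 0.01, 0.1, 0.06, 0.005, 0.25, 0.03, 0.05, 2.0],
        "fp1": [2.0, 0.125, 0.13, 0.05, 0.04, 0.26, 0.03, 0.05, 0.25],
        "emp1": [0.01, 0.2, 0.12, 0.07, 0.005, 0.24, 0.03, 0.05, 1.0],
        "efp1": [0.25, 0.125, 0.11, 0.06, 0.125, 0.25, 0.03, 0.05, 0.25],
    }
    genes = [
        "foxl2", "c43476", "c45042", "c19309", "c54338",
        "vit6", "zglp1", "dmrt", "fem1-like",
    ]
    return RelExprTable(values=pd.DataFrame.from_dict(rows, orient="index", columns=genes))
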