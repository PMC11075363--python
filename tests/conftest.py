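import numpy as np
import pandas as pd
import pytest

from pcomics.simulate import SimConfig, gen_cargo_fixture


@pytest.fixture(scope="session")
def cargo_fixture():
    """One shared noiseless cargo fixture (expression, accessibility, UTRs, reads)."""
    return gen_cargo_fixture(SimConfig(seed=7))


@pytest.fixture()
def small_beta_table():
    """200-CpG table, 5 vs 5 samples, no planted effect, with a few NaNs."""
    rng = np.random.default_rng(11)
    n = 200
    pos = 1000 + np.cumsum(rng.integers(10, 80, size=n))
    data = {"chrom": "chr1", "pos": pos}
    groups = {}
    for grp in ("PE", "nonPE"):
        for i in range(5):
            s = f"{grp}_{i}"
            v = rng.beta(10, 10, size=n)
            v[rng.random(n) < 0.02] = np.nan
            data[s] = v
            groups[s] = grp
    return pd.DataFrame(data), groups
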