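import numpy as np
import pandas as pd
import pytest

from primerbias import synthgen


@pytest.fixture(scope="session")
def small_truth():
    return synthgen.simulate_truth(
        n_taxa=60, habitats={"water": 4, "soil": 5, "gut": 3}, seed=11
    )


@pytest.fixture(scope="session")
def paired_dataset(small_truth):
    """Small paired two-primer observation of the small truth."""
    pa = synthgen.make_primer_profile(small_truth, "V4", efficiency_sigma=0.5, seed=1)
    pb = synthgen.make_primer_profile(
        small_truth, "V5V7", coverage_fraction=0.8, efficiency_sigma=0.5, seed=2
    )
    ta, ma = synthgen.apply_primer(small_truth, pa, depth=5000, seed=3)
    tb, mb = synthgen.apply_primer(small_truth, pb, depth=5000, seed=4)
    table = pd.concat([ta, tb]).fillna(0).astype(int)
    meta = pd.concat([ma, mb])
    return table, meta


@pytest.fixture
def rng():
    return np.random.default_rng(7)
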