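import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20130411)


@pytest.fixture(scope="session")
def est_fixture():
    """A moderately rich synthetic EST set shared across test modules."""
    from estssr import simulate as sim

    spec = sim.EstSetSpec(seed=101, n_plain=8, n_duplicates=4,
                          n_contaminants_per_class=1, n_short=2,
                          n_polya_tails=2, n_compound_pairs=2)
    records, contaminants, truth = sim.make_est_set(spec)
    return records, contaminants, truth
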