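import numpy as np
import pytest

from neurokda.synth import SynthSpec, generate_cohort


@pytest.fixture
def small_cohort():
    """A small, clean two-class cohort with planted structure."""
    spec = SynthSpec(
        n_per_class=(10, 10), dim=60, rank_class=2, rank_confound=3,
        sparsity=0.05, effect=3.0, noise_sd=0.0, seed=1,
    )
    return generate_cohort(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
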