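import numpy as np
import pytest

import hashdemux as hd


@pytest.fixture(scope="session")
def small_simulated():
    """Well-separated 2-HTO dataset reused by several modules."""
    return hd.generate_dataset(
        m=1500,
        n=2,
        signal_params=hd.nbreg_params(1450, 0.6, 10),
        background_params=hd.nbreg_params(25, 0.0, 5),
        class_probs=[0.45, 0.45],
        msm_prob=0.05,
        seed=11,
    )


@pytest.fixture(scope="session")
def naive_mixture_counts():
    """Counts from a covariate-free two-component NB mixture with known truth."""
    rng = np.random.default_rng(7)
    m = 4000
    positive = rng.random(m) < 0.4
    y = np.where(
        positive,
        rng.negative_binomial(10, 10 / (10 + 2000), size=m),
        rng.negative_binomial(5, 5 / (5 + 20), size=m),
    )
    x = np.maximum(np.rint(rng.lognormal(np.log(1800), 0.5, m)), 50).astype(np.int64)
    return y, x, positive
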