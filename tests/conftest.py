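import numpy as np
import pytest

from tgdrsurv import SurvivalDataset


@pytest.fixture
def two_sample_events():
    """Two samples, both events, distinct times."""
    return SurvivalDataset(Z=np.zeros((2, 1)), time=[1.0, 2.0], event=[1, 1])


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_survival_data(rng, n, p, censor_frac=0.3, tie_frac=0.0):
    """Small random dataset for oracle comparisons."""
    Z = rng.standard_normal((n, p))
    time = rng.exponential(scale=5.0, size=n) + 0.01
    if tie_frac > 0:
        k = max(2, int(tie_frac * n))
        idx = rng.choice(n, size=k, replace=False)
        time[idx] = time[idx[0]]
    event = (rng.uniform(size=n) > censor_frac).astype(int)
    if event.sum() == 0:
        event[0] = 1
    return SurvivalDataset(Z=Z, time=time, event=event)
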