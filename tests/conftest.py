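import numpy as np
import pytest

from nphtrial import TrialDataset


@pytest.fixture
def toy_dataset() -> TrialDataset:
    """Five subjects: control events at 1 and 3 plus a censoring at 4;
    treatment event at 3 plus a censoring at 2.

    Hand-enumerated risk sets at the unique event times 1 and 3:
    Y0 = (3, 2), Y1 = (2, 1), dN0 = (1, 1), dN1 = (0, 1).
    """
    return TrialDataset(
        recruit_time=[0.0] * 5,
        obs_time=[1.0, 3.0, 4.0, 3.0, 2.0],
        event=[True, True, False, True, False],
        arm=[0, 0, 0, 1, 1],
    )


def random_dataset(rng: np.random.Generator, n: int = 60, censor_frac: float = 0.3) -> TrialDataset:
    """Small random two-arm dataset with ties, for property tests."""
    obs = rng.integers(1, 15, size=n).astype(float)  # integer times force ties
    event = rng.uniform(size=n) > censor_frac
    arm = (rng.uniform(size=n) < 0.5).astype(int)
    # guarantee both arms and at least one event
    arm[0], arm[1] = 0, 1
    event[0] = True
    return TrialDataset(recruit_time=np.zeros(n), obs_time=obs, event=event, arm=arm)
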