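import warnings

import numpy as np
import pytest

warnings.filterwarnings("ignore", category=FutureWarning)

from tvatoj.studies import recovery_study  # noqa: E402


@pytest.fixture(scope="session")
def recovery():
    """The verification cohort fit: 15 participants x 244 trials, known truth.

    Shared across the recovery, shrinkage and transform-safety tests; the
    fit itself takes about a minute.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return recovery_study(seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
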