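import warnings

import numpy as np
import pytest

from addhrvr import IbiSeries

# statsmodels mixed models on small simulated datasets routinely sit on the
# variance-component boundary; that is expected, not a test failure signal
warnings.filterwarnings("ignore", module="statsmodels")
warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_uniform_series(ibi_ms=800.0, start=9 * 3600, duration_s=600.0,
                        person_id="p0", day=0) -> IbiSeries:
    """Perfectly regular beat stream starting at ``start``."""
    n = int(duration_s * 1000 / ibi_ms)
    ibis = np.full(n, float(ibi_ms))
    t = start + np.concatenate([[0.0], np.cumsum(ibis[:-1])]) / 1000.0
    return IbiSeries(person_id=person_id, day=day, t=t, ibi=ibis)


@pytest.fixture
def uniform_series():
    return make_uniform_series()


@pytest.fixture(scope="session")
def small_study():
    """One small simulated trial shared by evaluation tests."""
    from addhrvr import simulate_study

    return simulate_study(n_persons=12, n_days=2, seed=20240901)


@pytest.fixture(scope="session")
def small_windows(small_study):
    from addhrvr import build_windows

    st = small_study
    return build_windows(st.minutes[st.minutes["day"] > 0], st.prompts)
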