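import numpy as np
import pandas as pd
import pytest

from lcrisk.synthetic_cohort import GeneratorConfig, generate, generate_with_missingness


@pytest.fixture(scope="session")
def default_cohort():
    """A 30,000-participant default cohort with missingness injected."""
    return generate_with_missingness(GeneratorConfig(n_participants=30_000, seed=11))


@pytest.fixture(scope="session")
def exponential_survival():
    """Exponential event times (rate e^-5) censored at 7 years, n=20,000."""
    rng = np.random.default_rng(42)
    n = 20_000
    t = rng.exponential(np.exp(5.0), n)
    time = np.minimum(t, 7.0)
    return pd.DataFrame({"time": time, "event": (t <= 7.0).astype(int)})
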