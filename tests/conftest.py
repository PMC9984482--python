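import math

import numpy as np
import pytest
from hypothesis import settings

# deterministic hypothesis runs: same example sequence every invocation
settings.register_profile("det", derandomize=True, max_examples=100, deadline=None)
settings.load_profile("det")


def naive_ppv(pp):
    """Brute-force loop evaluation of the six printed variability formulas.

    Deliberately independent of the package implementation: pure-Python
    accumulation, no numpy on the hot path. Returns a dict keyed like
    PPVIndexSet.as_dict().
    """
    n = len(pp)
    assert n >= 2
    mean = sum(pp) / n
    sd = math.sqrt(sum((x - mean) ** 2 for x in pp) / (n - 1))
    cv = 100.0 * sd / mean
    sq, ab, mx = 0.0, 0.0, 0.0
    for i in range(n - 1):
        d = pp[i + 1] - pp[i]
        sq += d * d
        ab += abs(d)
        mx = max(mx, abs(d))
    return {
        "mean_pp": mean,
        "sd": sd,
        "cv": cv,
        "sv": math.sqrt(sq / (n - 1)),
        "arv": ab / (n - 1),
        "dmm": max(pp) - min(pp),
        "msc": mx,
    }


def random_pp_series(rng: np.random.Generator, n_min=2, n_max=30):
    n = int(rng.integers(n_min, n_max + 1))
    return rng.uniform(20.0, 120.0, size=n).tolist()


@pytest.fixture(scope="session")
def tiny_cohort():
    from ppvstroke.synthetic_data import make_fixture

    return make_fixture("tiny_cohort_n20")


@pytest.fixture(scope="session")
def default_cohort():
    from ppvstroke.synthetic_data import SyntheticCohortSpec, generate_cohort

    return generate_cohort(SyntheticCohortSpec(seed=1234))
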