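import math

import numpy as np
import pytest

from htnorm.types import CountPair


def brute_binomial_pvalue(y1: int, y2: int, p0: float) -> float:
    """Independent enumeration oracle for the two-sided exact tail.

    Sums binomial pmf terms (plain comb * powers, no scipy tails) over all
    outcomes at least as far from the conditional mean p0*n as observed.
    """
    n = y1 + y2
    mean = p0 * n
    d = abs(y1 - mean)
    total = 0.0
    for x in range(n + 1):
        if abs(x - mean) >= d - 1e-9 * (1.0 + mean + d):
            total += math.comb(n, x) * p0 ** x * (1.0 - p0) ** (n - x)
    return min(total, 1.0)


def null_hk_pair(m: int = 500, true_c: float = 1.0, seed: int = 0,
                 mean_range=(50, 500), N: int = 1_000_000) -> CountPair:
    """Null housekeeping counts at a known scaling factor.

    Under the null the expected depth-normalized count of library 1 is
    ``true_c`` times that of library 2, so with equal forced depths the
    library-1 means are ``true_c * mu``.
    """
    rng = np.random.default_rng(seed)
    mu = rng.uniform(*mean_range, size=m)
    y1 = rng.poisson(true_c * mu)
    y2 = rng.poisson(mu)
    return CountPair(tuple(f"hk{i}" for i in range(m)), y1, y2, N, N)


@pytest.fixture
def toy_pair():
    return CountPair(("a", "b", "c", "d"), [10, 20, 5, 0], [12, 18, 5, 0],
                     1000, 1000)
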