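"""Small MCMC building blocks shared by the model modules.

Both models in this package are conditionally conjugate given their scale
parameters, so they are fitted by Gibbs sampling with exact full
conditionals; the one non-conjugate scalar (the half-Normal-prior residual
SD of the treatment model) is updated by univariate slice sampling
(stepping-out and shrinkage), which requires no tuning.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
from scipy import stats

__all__ = ["slice_sample", "truncated_normal", "spawn_seeds"]


def slice_sample(
    x0: float,
    logpdf: Callable[[float], float],
    rng: np.random.Generator,
    width: float = 1.0,
    max_steps: int = 50,
    lower: float = -np.inf,
    upper: float = np.inf,
) -> float:
    """One univariate slice-sampling update (stepping-out + shrinkage)."""
    logy = logpdf(x0) + np.log(rng.uniform())
    u = rng.uniform()
    left = max(x0 - u * width, lower)
    right = min(left + width, upper)
    j = int(rng.integers(0, max_steps))
    k = max_steps - 1 - j
    while j > 0 and left > lower and logpdf(left) > logy:
        left = max(left - width, lower)
        j -= 1
    while k > 0 and right < upper and logpdf(right) > logy:
        right = min(right + width, upper)
        k -= 1
    while True:
        x1 = rng.uniform(left, right)
        if logpdf(x1) > logy:
            return x1
        if x1 < x0:
            left = x1
        else:
            right = x1


def truncated_normal(
    mean: np.ndarray,
    sd: float | np.ndarray,
    upper: float | np.ndarray,
    rng: np.random.Generator,
    lower: float | np.ndarray = -np.inf,
) -> np.ndarray:
    """Draw from Normal(mean, sd) truncated to (lower, upper), elementwise.

    Numerically robust in far tails (delegates to scipy's truncnorm).
    """
    mean = np.atleast_1d(np.asarray(mean, dtype=float))
    a = (np.asarray(lower, dtype=float) - mean) / sd
    b = (np.asarray(upper, dtype=float) - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng)


def spawn_seeds(seed: int, n: int, salt: int = 0) -> list[int]:
    """Derive ``n`` independent 31-bit integer seeds from one master seed."""
    ss = np.random.SeedSequence((int(seed), int(salt)))
    return [int(s) % (2**31) for s in ss.generate_state(n, dtype=np.uint64)]
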