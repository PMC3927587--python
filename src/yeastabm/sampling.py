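"""Truncated-normal sampling of individually randomized parameters.

Per-cell parameters (budding threshold m_b0, expression randomization
factors, maximum growth rate, damage exponent) are drawn at birth from a
global truncated normal with configured mean and sd = mean * CV, truncated
to (0, mean + 3 sd].  Sampling is by rejection, which leaves the shape of
the parent normal intact inside the window.  A CV of zero degenerates to the
exact mean and consumes no random numbers (so that switching an absent
source on/off cannot shift the random stream).
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .exceptions import ConfigurationError


def truncated_normal(mean: float, cv: float, size=None, rng=None):
    """Draw from the global truncated normal (rejection sampling).

    Returns a float when ``size`` is None, else an ndarray of that size.
    Every draw is strictly positive and at most ``mean + 3*sd``.
    """
    if cv < 0:
        raise ConfigurationError(f"negative CV {cv}")
    if mean <= 0:
        raise ConfigurationError(f"truncated normal needs mean > 0, got {mean}")
    scalar = size is None
    n = 1 if scalar else int(size)
    if cv == 0.0 or n == 0:
        out = np.full(n, float(mean))
        return float(out[0]) if scalar else out
    if rng is None:
        rng = np.random.default_rng()
    sd = mean * cv
    upper = mean + 3.0 * sd
    out = np.empty(n)
    filled = 0
    while filled < n:
        # acceptance prob is >= Phi(3) - Phi(-1/cv) ~ 0.5, so a 2x batch
        # nearly always finishes in one or two passes
        batch = max(2 * (n - filled), 16)
        x = rng.normal(mean, sd, size=batch)
        x = x[(x > 0.0) & (x <= upper)]
        take = min(x.size, n - filled)
        out[filled:filled + take] = x[:take]
        filled += take
    return float(out[0]) if scalar else out


def truncated_normal_mean(mean: float, cv: float) -> float:
    """Analytic mean of the same truncated normal (used by mean-preserving
    ablations, and as an independent check of the rejection sampler)."""
    if cv < 0:
        raise ConfigurationError(f"negative CV {cv}")
    if cv == 0.0:
        return float(mean)
    sd = mean * cv
    a = (0.0 - mean) / sd      # lower bound 0 in standard units
    b = 3.0                    # upper bound mean + 3 sd
    return float(stats.truncnorm.mean(a, b, loc=mean, scale=sd))
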